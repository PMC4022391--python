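"""End-to-end pipeline: annotations -> enrichment -> pathway scores ->
metabolism network -> motifs, with all stage outputs written as TSV/JSON.

The default settings reproduce the standard analysis: e-value < 1e-5
annotation filter (plus identity > 75 for short-read paired designs when
requested), enrichment threshold P < 1e-4 with no multiple-testing
correction, motif constraints 4/3/1, Welch t-test, merged-target distance
shells with the two top-scoring pathways as targets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import annotations as anno
from . import enrichment as enr
from . import metabnet as net
from . import motifs as mot
from . import pathways as pw
from .synthdata import SynthConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("viromet")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for exit reporting."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully resolved run parameters; defaults are the standard settings."""

    # inputs: either file paths ...
    background: str | None = None
    subset: str | None = None
    cluster_mapping: str | None = None
    universe: str | None = None
    reactions_dir: str | None = None
    # ... or a synthetic scenario
    synthetic: SynthConfig | None = None
    # filters
    max_e_value: float = 1e-5
    min_identity: float | None = None
    count_mode: str = "per_ko"
    # enrichment
    alpha: float = 1e-4
    design: str = "superset"
    adjust: str = "none"
    # pathway scoring
    p_floor: float = 1e-300
    # network analysis
    distance_mode: str = "merged"
    equal_var: bool = False
    exclude_compounds: tuple[str, ...] = ()
    n_targets: int = 2
    # motifs
    motif_min_len: int = 4
    motif_min_enriched: int = 3
    motif_max_nonenriched: int = 1
    motif_alpha: float = 0.05
    motif_mode: str = "pmf"
    motif_include_first: bool = False
    motif_direction: str = "forward"
    # output
    outdir: str = "viromet_out"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the summary dictionary.

    Outputs under ``config.outdir``: the resolved config, per-stage TSVs
    (KO counts, enrichment table, pathway report, network exports, shell
    report, motif report) and ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "w") as handle:
        json.dump(config.resolved(), handle, indent=2, default=str)
    log.info("resolved config written to %s", outdir / "run_config.json")

    summary: dict = {"stages": {}}
    timings: dict[str, float] = {}

    def timed(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        return out

    # ---- inputs -----------------------------------------------------------
    def load_inputs():
        if config.synthetic is not None:
            ds = generate_dataset(config.synthetic)
            write_dataset(ds, outdir / "inputs")
            reaction_dir = outdir / "inputs" / "reactions"
            return ds.background, ds.subset, ds.mapping, ds.universe, reaction_dir
        for label, path in (
            ("background", config.background),
            ("subset", config.subset),
            ("universe", config.universe),
        ):
            if path is None:
                raise FileNotFoundError(f"no {label} input configured")
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} input not found: {path}")
        background = anno.read_annotation_table(
            config.background, anno.CANONICAL_DIALECT, dataset_label="background"
        )
        subset = anno.read_annotation_table(
            config.subset, anno.CANONICAL_DIALECT, dataset_label="viral_subset"
        )
        if config.cluster_mapping and Path(config.cluster_mapping).exists():
            mapping = anno.ClusterMapping.read_tsv(config.cluster_mapping)
        else:
            mapping = anno.ClusterMapping({})
        universe = pw.load_pathway_definitions(config.universe)
        rdir = Path(config.reactions_dir) if config.reactions_dir else None
        return background, subset, mapping, universe, rdir

    background, subset, mapping, universe, reactions_dir = timed("inputs", load_inputs)

    # ---- annotations ------------------------------------------------------
    def annotations_stage():
        sub = anno.expand_clusters(subset, mapping)
        sub = anno.filter_annotations(sub, config.max_e_value, config.min_identity)
        bg = anno.filter_annotations(background, config.max_e_value, config.min_identity)
        sub_counts = anno.count_kos(sub, mode=config.count_mode)
        bg_counts = anno.count_kos(bg, mode=config.count_mode)
        sub_counts.write_tsv(outdir / "subset_ko_counts.tsv")
        bg_counts.write_tsv(outdir / "background_ko_counts.tsv")
        return sub, bg, sub_counts, bg_counts

    sub_f, bg_f, sub_counts, bg_counts = timed("annotations", annotations_stage)
    summary["stages"]["annotations"] = {
        "background_records_raw": len(background),
        "subset_records_raw": len(subset),
        "background_records_filtered": len(bg_f),
        "subset_records_filtered": len(sub_f),
        "n_clusters_expanded": len(mapping),
    }

    # ---- enrichment -------------------------------------------------------
    def enrichment_stage():
        calls = enr.call_enriched_kos(
            sub_counts, bg_counts, design=config.design, alpha=config.alpha
        )
        calls = enr.adjust_pvalues(calls, method=config.adjust)
        enr.write_enrichment_tsv(calls, outdir / "enrichment.tsv")
        return calls

    calls = timed("enrichment", enrichment_stage)
    enriched_calls = [c for c in calls if c.enriched]
    summary["stages"]["enrichment"] = {
        "n_kos_tested": len(calls),
        "n_kos_enriched": len(enriched_calls),
        "alpha": config.alpha,
        "design": config.design,
    }

    # ---- pathways ---------------------------------------------------------
    def pathway_stage():
        report = pw.build_pathway_report(universe, calls, p_floor=config.p_floor)
        pw.report_frame(report).to_csv(
            outdir / "pathway_report.tsv", sep="\t", index=False
        )
        return report

    report = timed("pathways", pathway_stage)
    summary["stages"]["pathways"] = {"n_pathways_scored": len(report)}

    # ---- metabolism network ----------------------------------------------
    def network_stage():
        enriched_pathways = frozenset(r.pathway_id for r in report)
        network = net.build_network(
            universe,
            enriched=enriched_pathways,
            exclude_compounds=config.exclude_compounds,
        )
        net.export_network(network, outdir / "network.graphml", fmt="graphml")
        net.export_network(network, outdir / "network_edges.tsv", fmt="edgelist")
        stats: dict = {
            "n_nodes": network.graph.number_of_nodes(),
            "n_edges": network.n_edges,
            "n_enriched_nodes": len(network.enriched),
        }
        order, vector = net.rank_by_degree(network)
        if vector.sum() >= 1:
            mhg = net.mhg_statistic_and_pvalue(vector)
            stats["mhg"] = {
                "statistic": mhg.mhg_statistic,
                "cutoff_index": mhg.cutoff_index,
                "p_value": mhg.p_value,
            }
        if network.enriched and set(order) - network.enriched:
            stats["degree_comparison"] = net.compare_degree_distributions(network)
        targets = [r.pathway_id for r in report[: config.n_targets]]
        if targets:
            shells = net.distance_shells(network, targets, mode=config.distance_mode)
            per_shell = net.shell_enrichment(shells, network.enriched)
            with open(outdir / "distance_shells.tsv", "w") as handle:
                handle.write("distance\tn_pathways\tn_enriched\tp_value\n")
                for d, row in per_shell.items():
                    handle.write(
                        f"{d}\t{row['n_pathways']}\t{row['n_enriched']}\t{row['p_value']!r}\n"
                    )
            stats["targets"] = targets
            stats["n_unreachable"] = len(shells.unreachable)
            try:
                stats["distance_comparison"] = net.compare_distance_distributions(
                    shells, network.enriched, equal_var=config.equal_var
                )
            except ValueError:
                stats["distance_comparison"] = None
        with open(outdir / "network_stats.json", "w") as handle:
            json.dump(stats, handle, indent=2, default=str)
        return network, stats

    network, net_stats = timed("metabnet", network_stage)
    summary["stages"]["metabnet"] = {
        k: v for k, v in net_stats.items() if k in ("n_nodes", "n_edges", "n_enriched_nodes")
    }
    if "mhg" in net_stats:
        summary["stages"]["metabnet"]["mhg_p_value"] = net_stats["mhg"]["p_value"]

    # ---- motifs -----------------------------------------------------------
    def motif_stage():
        enriched_kos = frozenset(c.ko_id for c in enriched_calls)
        all_motifs: list[mot.Motif] = []
        if reactions_dir is not None and Path(reactions_dir).is_dir():
            for path in sorted(Path(reactions_dir).glob("*.tsv")):
                graph = mot.load_reaction_graph(path, enriched_kos)
                if not len(graph):
                    continue
                motifs = mot.find_motifs(
                    graph,
                    min_len=config.motif_min_len,
                    min_enriched=config.motif_min_enriched,
                    max_nonenriched=config.motif_max_nonenriched,
                    direction=config.motif_direction,
                )
                all_motifs.extend(
                    mot.score_motifs(
                        motifs,
                        graph,
                        mode=config.motif_mode,
                        include_first=config.motif_include_first,
                    )
                )
        frame = mot.motif_report_frame(all_motifs, alpha=config.motif_alpha)
        frame.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        return all_motifs

    all_motifs = timed("motifs", motif_stage)
    summary["stages"]["motifs"] = {
        "n_motifs": len(all_motifs),
        "n_significant": sum(
            1 for m in all_motifs if m.p_value is not None and m.p_value < config.motif_alpha
        ),
    }

    summary["timings_s"] = timings
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2)
    log.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary
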