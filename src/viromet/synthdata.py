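"""Synthetic metagenome-annotation data with planted enrichment.

The generator emulates the statistical shape of the real inputs so every
pipeline stage can be exercised and validated without any download:

* a pathway universe (default 148 pathways, mirroring the number of KEGG
  metabolic pathways) whose members are drawn from a shared KO pool and
  whose substrate/product sets are drawn from a shared compound pool, so
  a compound-sharing network of realistic connectivity emerges;
* a small reaction graph per pathway (a substrate-to-product backbone
  chain plus side branches);
* a background metagenome of (read, KO) annotations with heavy-tailed
  (log-uniform) KO abundances, and either a literal read subset re-weighted
  towards planted KOs (superset design) or an independently drawn
  virome/microbiome pair (paired design);
* e-values and identities drawn so a known fraction of records fails the
  standard quality filters, and a configurable fraction of subset reads
  wrapped into similarity clusters to exercise cluster expansion.

Every artifact is a deterministic function of the seed, and the returned
:class:`GroundTruth` ledger records the planted KOs, their folds, the
per-KO probabilities and the exact post-expansion count tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, ClusterMapping, COLUMNS, _dedupe
from .motifs import Reaction, ReactionGraph, write_reaction_graph
from .pathways import PathwayDef, PathwayUniverse

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "generate_universe",
    "generate_metagenome_pair",
    "generate_dataset",
    "expected_edge_count",
    "write_dataset",
]


@dataclass
class SynthConfig:
    """Study conditions of the simulated comparison.

    Defaults describe the reference scenario used throughout the tests:
    a 148-pathway universe over a 2,000-KO pool, a 200,000-annotation
    background with a 2,000-annotation viral subset, and 10 planted KOs at
    20-fold enrichment drawn from the abundant end of the background law
    (log10 weight in ``planted_log10_weight_range``), which is the
    generator's stated detectable-effect regime.
    """

    seed: int = 0
    # universe
    n_pathways: int = 148
    kos_per_pathway: tuple[int, int] = (10, 60)
    ko_pool_size: int = 2000
    compound_pool_size: int = 300
    substrates_per_pathway: tuple[int, int] = (2, 6)
    products_per_pathway: tuple[int, int] = (2, 6)
    reactions_per_pathway: tuple[int, int] = (6, 14)
    # metagenomes
    design: str = "superset"
    n_background_reads: int = 200_000
    n_subset_reads: int = 2_000
    n_planted: int = 10
    planted_fold: float = 20.0
    planted_kos: tuple[tuple[str, float], ...] | None = None
    abundance_log10_range: tuple[float, float] = (0.0, 3.0)
    planted_log10_weight_range: tuple[float, float] = (2.0, 3.0)
    evalue_log10_range: tuple[float, float] = (-20.0, -3.0)
    identity_range: tuple[float, float] = (50.0, 100.0)
    multi_ko_fraction: float = 0.02
    cluster_fraction: float = 0.1
    cluster_size_range: tuple[int, int] = (2, 4)

    def validate(self) -> None:
        if self.n_pathways < 0 or self.n_background_reads < 0 or self.n_subset_reads < 0:
            raise ValueError("sizes must be non-negative")
        if self.kos_per_pathway[1] > self.ko_pool_size:
            raise ValueError(
                f"a pathway may need {self.kos_per_pathway[1]} KOs but the pool "
                f"holds only {self.ko_pool_size}"
            )
        if max(self.substrates_per_pathway[1], self.products_per_pathway[1]) > (
            self.compound_pool_size
        ):
            raise ValueError("compound pool smaller than per-pathway compound draw")
        if self.planted_fold < 1:
            raise ValueError("planted fold must be >= 1")
        if self.planted_kos is not None and any(f < 1 for _, f in self.planted_kos):
            raise ValueError("planted folds must be >= 1")
        if self.design not in ("superset", "paired"):
            raise ValueError(f"unknown design: {self.design!r}")
        if self.design == "superset" and self.n_subset_reads > self.n_background_reads:
            raise ValueError("subset larger than background in superset design")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted: dict[str, float] = field(default_factory=dict)
    background_probs: dict[str, float] = field(default_factory=dict)
    background_counts: dict[str, int] = field(default_factory=dict)
    subset_counts: dict[str, int] = field(default_factory=dict)
    subset_counts_filtered: dict[str, int] = field(default_factory=dict)
    background_counts_filtered: dict[str, int] = field(default_factory=dict)
    hot_pathways: dict[str, int] = field(default_factory=dict)
    notes: str = ""


@dataclass
class SynthDataset:
    universe: PathwayUniverse
    reaction_graphs: dict[str, ReactionGraph]
    background: AnnotationSet
    subset: AnnotationSet
    mapping: ClusterMapping
    ground_truth: GroundTruth
    config: SynthConfig


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def generate_universe(
    cfg: SynthConfig,
) -> tuple[PathwayUniverse, dict[str, ReactionGraph], GroundTruth]:
    """Draw the pathway universe, per-pathway reaction graphs, and the
    planted-KO ground truth.

    Planted KOs are concentrated in a few "hot" pathways (recorded in the
    ground truth) so pathway-level recovery is well defined; within hot
    pathways the planted KOs label consecutive backbone reactions, planting
    detectable motif chains.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    kos = [f"K{i + 1:05d}" for i in range(cfg.ko_pool_size)]
    compounds = [f"C{i + 1:05d}" for i in range(cfg.compound_pool_size)]

    pathways = []
    for i in range(cfg.n_pathways):
        pid = f"syn{i + 1:05d}"
        size = _randint(rng, cfg.kos_per_pathway)
        members = rng.choice(cfg.ko_pool_size, size=size, replace=False)
        n_sub = _randint(rng, cfg.substrates_per_pathway)
        n_prod = _randint(rng, cfg.products_per_pathway)
        subs = rng.choice(cfg.compound_pool_size, size=n_sub, replace=False)
        prods = rng.choice(cfg.compound_pool_size, size=n_prod, replace=False)
        pathways.append(
            PathwayDef(
                pathway_id=pid,
                name=f"Synthetic pathway {i + 1}",
                member_kos=frozenset(kos[m] for m in members),
                substrates=frozenset(compounds[c] for c in subs),
                products=frozenset(compounds[c] for c in prods),
            )
        )
    universe = PathwayUniverse(pathways)

    gt = GroundTruth()
    if cfg.planted_kos is not None:
        gt.planted = {ko: float(f) for ko, f in cfg.planted_kos}
        member_union = set().union(*(p.member_kos for p in pathways)) if pathways else set()
        missing = set(gt.planted) - member_union
        if missing:
            raise ValueError(f"planted KOs not in the universe: {sorted(missing)[:3]}")
        for p in pathways:
            n_hot = len(p.member_kos & set(gt.planted))
            if n_hot:
                gt.hot_pathways[p.pathway_id] = n_hot
    elif cfg.n_planted > 0 and pathways:
        order = rng.permutation(cfg.n_pathways)
        for idx in order:
            if len(gt.planted) >= cfg.n_planted:
                break
            p = pathways[idx]
            take = min(4, cfg.n_planted - len(gt.planted), len(p.member_kos))
            chosen = sorted(p.member_kos - set(gt.planted))
            picked = [
                chosen[j]
                for j in rng.choice(len(chosen), size=min(take, len(chosen)), replace=False)
            ]
            if picked:
                gt.hot_pathways[p.pathway_id] = len(picked)
                for ko in picked:
                    gt.planted[ko] = cfg.planted_fold

    graphs: dict[str, ReactionGraph] = {}
    planted_set = set(gt.planted)
    for p in pathways:
        n_rxn = _randint(rng, cfg.reactions_per_pathway)
        n_backbone = max(4, n_rxn - 2)
        members = sorted(p.member_kos)
        start = sorted(p.substrates)[0] if p.substrates else f"{p.pathway_id}_c0"
        end = sorted(p.products)[0] if p.products else f"{p.pathway_id}_cZ"
        chain_compounds = (
            [start]
            + [f"{p.pathway_id}_m{j}" for j in range(1, n_backbone)]
            + [end]
        )
        hot_members = sorted(set(members) & planted_set)
        reactions = []
        for j in range(n_backbone):
            # hot pathways: planted KOs label consecutive backbone steps
            if hot_members and j < len(hot_members):
                ko = hot_members[j]
            else:
                ko = members[int(rng.integers(len(members)))]
            reactions.append(
                Reaction(
                    reaction_id=f"{p.pathway_id}_r{j + 1}",
                    substrate=chain_compounds[j],
                    product=chain_compounds[j + 1],
                    kos=frozenset([ko]),
                    enriched=ko in planted_set,
                )
            )
        all_cpds = set(chain_compounds)
        for j in range(n_backbone, n_rxn):
            anchor = chain_compounds[int(rng.integers(len(chain_compounds)))]
            branch = f"{p.pathway_id}_b{j}"
            ko = members[int(rng.integers(len(members)))]
            reactions.append(
                Reaction(
                    reaction_id=f"{p.pathway_id}_r{j + 1}",
                    substrate=anchor,
                    product=branch,
                    kos=frozenset([ko]),
                    enriched=ko in planted_set,
                )
            )
            all_cpds.add(branch)
        graphs[p.pathway_id] = ReactionGraph(
            pathway_id=p.pathway_id,
            compounds=frozenset(all_cpds),
            reactions=tuple(reactions),
        )
    return universe, graphs, gt


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Weighted sampling of n distinct indices (Efraimidis-Spirakis via
    Gumbel keys); O(N) and deterministic under the generator state."""
    if n > len(weights):
        raise ValueError("cannot sample more items than available")
    keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, n - 1)[:n] if n else np.empty(0, dtype=np.int64)


def _counts(kos: np.ndarray) -> dict[str, int]:
    uniq, cnt = np.unique(kos, return_counts=True)
    return {str(k): int(c) for k, c in zip(uniq, cnt)}


def generate_metagenome_pair(
    universe: PathwayUniverse,
    gt: GroundTruth,
    cfg: SynthConfig,
) -> tuple[AnnotationSet, AnnotationSet, ClusterMapping, GroundTruth]:
    """Draw the (reference, subset) annotation-set pair.

    Superset design: the subset is a literal subset of background reads,
    selected with weight proportional to the planted fold of each read's
    KO.  Paired design: the virome is an independent draw from the
    fold-re-weighted law.  Returns (background/microbiome, subset/virome,
    cluster mapping, updated ground truth).
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    all_kos = sorted(set().union(*(p.member_kos for p in universe)) if len(universe) else set())
    if not all_kos:
        raise ValueError("universe has no member KOs")
    ko_arr = np.array(all_kos)
    n_kos = len(all_kos)

    lo, hi = cfg.abundance_log10_range
    weights = 10 ** rng.uniform(lo, hi, size=n_kos)
    plo, phi = cfg.planted_log10_weight_range
    folds = np.ones(n_kos)
    for i, ko in enumerate(all_kos):
        if ko in gt.planted:
            weights[i] = 10 ** rng.uniform(plo, phi)
            folds[i] = gt.planted[ko]
    probs = weights / weights.sum()
    gt.background_probs = {ko: float(p) for ko, p in zip(all_kos, probs)}

    def draw_annotations(n_reads: int, prefix: str, law: np.ndarray):
        idx = rng.choice(n_kos, size=n_reads, p=law)
        read_ids = np.array([f"{prefix}{i + 1:08d}" for i in range(n_reads)])
        ev = 10 ** rng.uniform(*cfg.evalue_log10_range, size=n_reads)
        ident = rng.uniform(*cfg.identity_range, size=n_reads)
        # a small fraction of reads carries a second, distinct KO
        extra_mask = rng.random(n_reads) < cfg.multi_ko_fraction
        n_extra = int(extra_mask.sum())
        extra_idx = rng.choice(n_kos, size=n_extra, p=law)
        keep = extra_idx != idx[extra_mask]
        frames = [
            pd.DataFrame(
                {
                    "read_id": read_ids,
                    "ko_id": ko_arr[idx],
                    "e_value": ev,
                    "pct_identity": ident,
                    "dataset_label": prefix.rstrip("_"),
                }
            )
        ]
        if keep.any():
            sel = np.flatnonzero(extra_mask)[keep]
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_ids[sel],
                        "ko_id": ko_arr[extra_idx[keep]],
                        "e_value": 10 ** rng.uniform(*cfg.evalue_log10_range, size=len(sel)),
                        "pct_identity": rng.uniform(*cfg.identity_range, size=len(sel)),
                        "dataset_label": prefix.rstrip("_"),
                    }
                )
            )
        frame = pd.concat(frames, ignore_index=True)
        return frame, idx

    if cfg.design == "superset":
        bg_frame, bg_idx = draw_annotations(
            cfg.n_background_reads, f"S{cfg.seed}_R", probs
        )
        read_fold = folds[bg_idx]  # per-read selection weight (base KO's fold)
        chosen = np.sort(
            _weighted_sample_without_replacement(rng, read_fold, cfg.n_subset_reads)
        )
        chosen_ids = set(bg_frame["read_id"].iloc[chosen])
        sub_frame = bg_frame[bg_frame["read_id"].isin(chosen_ids)].copy()
        sub_frame["dataset_label"] = "viral_subset"
    else:
        bg_frame, _ = draw_annotations(cfg.n_background_reads, f"S{cfg.seed}_M", probs)
        vprobs = probs * folds
        vprobs = vprobs / vprobs.sum()
        sub_frame, _ = draw_annotations(cfg.n_subset_reads, f"S{cfg.seed}_V", vprobs)

    gt.background_counts = _counts(bg_frame["ko_id"].to_numpy())
    bg_pass = bg_frame["e_value"] < 1e-5
    gt.background_counts_filtered = _counts(bg_frame.loc[bg_pass, "ko_id"].to_numpy())

    # wrap a fraction of confidently-annotated subset records into clusters;
    # the cluster takes its members' minimum e-value, so expand-then-filter
    # never passes a record whose background copy fails the e-value filter
    mapping: dict[str, tuple[str, ...]] = {}
    sub_frame = sub_frame.reset_index(drop=True)
    if cfg.cluster_fraction > 0 and len(sub_frame):
        eligible = sub_frame.index[sub_frame["e_value"] < 1e-5].to_numpy()
        target = int(cfg.cluster_fraction * len(sub_frame))
        rng.shuffle(eligible)
        by_ko: dict[str, list[int]] = {}
        seen_reads: set[str] = set()
        for i in eligible:
            # a read may carry several KO records; cluster it at most once
            # so cluster member sets stay disjoint
            read = sub_frame.at[i, "read_id"]
            if read in seen_reads:
                continue
            seen_reads.add(read)
            by_ko.setdefault(sub_frame.at[i, "ko_id"], []).append(int(i))
        clustered_rows: list[int] = []
        cluster_records = []
        cid = 0
        for ko in sorted(by_ko):
            rows = by_ko[ko]
            while len(rows) >= 2 and len(clustered_rows) < target:
                size = min(_randint(rng, cfg.cluster_size_range), len(rows))
                if size < 2:
                    break
                members, rows = rows[:size], rows[size:]
                cid += 1
                cluster_id = f"aa90_{cid}"
                mapping[cluster_id] = tuple(
                    sub_frame.at[m, "read_id"] for m in members
                )
                cluster_records.append(
                    (
                        cluster_id,
                        ko,
                        float(min(sub_frame.at[m, "e_value"] for m in members)),
                        float(np.mean([sub_frame.at[m, "pct_identity"] for m in members])),
                        "viral_subset",
                    )
                )
                clustered_rows.extend(members)
            if len(clustered_rows) >= target:
                break
        if cluster_records:
            kept = sub_frame.drop(index=clustered_rows)
            # ledger of the expanded-equivalent records (members inherit the
            # cluster's e-value/identity on expansion)
            expanded_rows = []
            for (cluster_id, ko, ev, ident, label) in cluster_records:
                for read in mapping[cluster_id]:
                    expanded_rows.append((read, ko, ev, ident, label))
            expanded_frame = pd.concat(
                [kept, pd.DataFrame(expanded_rows, columns=COLUMNS)],
                ignore_index=True,
            )
            sub_emit = pd.concat(
                [kept, pd.DataFrame(cluster_records, columns=COLUMNS)],
                ignore_index=True,
            )
        else:
            expanded_frame = sub_frame
            sub_emit = sub_frame
    else:
        expanded_frame = sub_frame
        sub_emit = sub_frame

    gt.subset_counts = _counts(expanded_frame["ko_id"].to_numpy())
    sub_pass = expanded_frame["e_value"] < 1e-5
    gt.subset_counts_filtered = _counts(expanded_frame.loc[sub_pass, "ko_id"].to_numpy())
    gt.notes = f"design={cfg.design}; seed={cfg.seed}"

    background = AnnotationSet(_dedupe(bg_frame), provenance="synthetic background")
    subset = AnnotationSet(_dedupe(sub_emit.reset_index(drop=True)), provenance="synthetic subset")
    return background, subset, ClusterMapping(mapping), gt


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full bundle: universe, reaction graphs, metagenome pair, truth."""
    universe, graphs, gt = generate_universe(cfg)
    background, subset, mapping, gt = generate_metagenome_pair(universe, gt, cfg)
    return SynthDataset(
        universe=universe,
        reaction_graphs=graphs,
        background=background,
        subset=subset,
        mapping=mapping,
        ground_truth=gt,
        config=cfg,
    )


def expected_edge_count(cfg: SynthConfig) -> float:
    """Analytic expectation of the number of compound-sharing edges.

    Substrate and product sets are uniform draws without replacement from a
    pool of M compounds; the chance that two independent draws of sizes a
    and b avoid each other is C(M-a, b)/C(M, b).  Averaging over the
    uniform size ranges and squaring (the two edge-forming directions are
    independent) gives the per-pair edge probability.
    """
    M = cfg.compound_pool_size
    p_sizes = range(cfg.products_per_pathway[0], cfg.products_per_pathway[1] + 1)
    s_sizes = range(cfg.substrates_per_pathway[0], cfg.substrates_per_pathway[1] + 1)
    q = 0.0
    for a in p_sizes:
        for b in s_sizes:
            q += math.comb(M - a, b) / math.comb(M, b)
    q /= len(p_sizes) * len(s_sizes)
    p_edge = 1 - q * q
    return math.comb(cfg.n_pathways, 2) * p_edge


def write_dataset(ds: SynthDataset, outdir) -> dict[str, str]:
    """Serialise every artifact as TSV/JSON under ``outdir``; returns the
    path map.  File dialects match what the readers consume."""
    from .annotations import write_annotation_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "background": str(outdir / "background.tsv"),
        "subset": str(outdir / "subset.tsv"),
        "cluster_mapping": str(outdir / "clusters.tsv"),
        "universe": str(outdir / "universe.tsv"),
        "reactions_dir": str(outdir / "reactions"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_annotation_table(ds.background, paths["background"])
    write_annotation_table(ds.subset, paths["subset"])
    ds.mapping.write_tsv(paths["cluster_mapping"])
    ds.universe.write_tsv(paths["universe"])
    rdir = Path(paths["reactions_dir"])
    rdir.mkdir(exist_ok=True)
    for pid, graph in ds.reaction_graphs.items():
        write_reaction_graph(graph, rdir / f"{pid}.tsv")
    pd.DataFrame(
        {
            "ko_id": list(ds.ground_truth.planted),
            "fold": list(ds.ground_truth.planted.values()),
        }
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    manifest = {
        "seed": ds.config.seed,
        "config": dataclasses.asdict(ds.config),
        "n_background_records": len(ds.background),
        "n_subset_records": len(ds.subset),
        "n_clusters": len(ds.mapping),
    }
    with open(paths["manifest"], "w") as handle:
        json.dump(manifest, handle, indent=2, default=list)
    return paths
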