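"""Pathway definitions and the pathway enrichment score.

A pathway is a named set of member ortholog groups (KOs) plus the compound
sets it consumes (substrates) and produces (products).  The pathway
enrichment score aggregates the evidence of a pathway's enriched member
KOs::

    ES = N * sum_{n=1..N} -log10(P_n) / T

where N is the number of member KOs called enriched, P_n their enrichment
p-values, and T the total number of KOs in the pathway.  ES is zero iff no
member KO is enriched, grows with both the number and the strength of the
enriched members, and is normalised by pathway size so large pathways are
not favoured.  A KO belonging to several pathways contributes its full
weight to each of them.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .annotations import _open
from .enrichment import KOEnrichment

__all__ = [
    "PathwayDef",
    "PathwayUniverse",
    "PathwayEnrichment",
    "load_pathway_definitions",
    "pathway_enrichment_score",
    "build_pathway_report",
    "report_frame",
]


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    member_kos: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("empty pathway_id")
        if not self.member_kos:
            raise ValueError(f"pathway {self.pathway_id} has no member KOs")

    @property
    def T(self) -> int:
        """Total number of member KOs."""
        return len(self.member_kos)


class PathwayUniverse:
    """A collection of uniquely-identified pathways with a KO -> pathways
    reverse index."""

    def __init__(self, pathways: Iterable[PathwayDef]):
        self._pathways: dict[str, PathwayDef] = {}
        self._ko_index: dict[str, list[str]] = {}
        for p in pathways:
            if p.pathway_id in self._pathways:
                raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
            self._pathways[p.pathway_id] = p
            for ko in p.member_kos:
                self._ko_index.setdefault(ko, []).append(p.pathway_id)
        for ko in self._ko_index:
            self._ko_index[ko].sort()

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[PathwayDef]:
        return iter(self._pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> PathwayDef:
        return self._pathways[pathway_id]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self._pathways)

    def pathways_for_ko(self, ko_id: str) -> list[str]:
        """Pathway ids whose member set contains ``ko_id``."""
        return list(self._ko_index.get(ko_id, []))

    def write_tsv(self, dest) -> None:
        with _open(dest, "w") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["pathway_id", "name", "member_kos", "substrates", "products"])
            for p in self._pathways.values():
                w.writerow(
                    [
                        p.pathway_id,
                        p.name,
                        ";".join(sorted(p.member_kos)),
                        ";".join(sorted(p.substrates)),
                        ";".join(sorted(p.products)),
                    ]
                )


def _parse_set(cell: str) -> frozenset[str]:
    return frozenset(x for x in cell.split(";") if x)


def load_pathway_definitions(source) -> PathwayUniverse:
    """Load a pathway-universe TSV: pathway_id, name, member_kos,
    substrates, products (semicolon-separated sets, header line)."""
    pathways = []
    with _open(source) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return PathwayUniverse([])
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns, got {len(row)}")
            members = _parse_set(row[2])
            if not members:
                raise ValueError(f"line {lineno}: pathway {row[0]!r} has no member KOs")
            pathways.append(
                PathwayDef(
                    pathway_id=row[0],
                    name=row[1],
                    member_kos=members,
                    substrates=_parse_set(row[3]),
                    products=_parse_set(row[4]),
                )
            )
    return PathwayUniverse(pathways)


def pathway_enrichment_score(
    enriched: Sequence[tuple[str, float]],
    T: int,
    p_floor: float | None = None,
) -> float:
    """Compute ES = N * sum(-log10 Pn) / T over the enriched member KOs.

    ``enriched`` is the list of (ko_id, p_value) pairs for member KOs
    called enriched; ``T`` is the pathway's total KO count.  A p-value of
    zero makes the score infinite and is a hard error; supply ``p_floor``
    (e.g. 1e-300) to clamp extreme p-values instead.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not enriched:
        return 0.0
    total = 0.0
    for ko, p in enriched:
        if p_floor is not None:
            p = max(p, p_floor)
        if p <= 0:
            raise ValueError(
                f"p-value {p!r} for {ko} is not in (0, 1]; set a p-value floor "
                "(p_floor) to keep the score finite"
            )
        if p > 1:
            raise ValueError(f"p-value {p!r} for {ko} exceeds 1")
        total += -math.log10(p)
    N = len(enriched)
    return N * total / T


@dataclass(frozen=True)
class PathwayEnrichment:
    """One scored pathway: its enriched member KOs (sorted by KO id) and ES."""

    pathway_id: str
    name: str
    enriched_kos: tuple[tuple[str, float], ...]
    es: float
    T: int

    @property
    def N(self) -> int:
        return len(self.enriched_kos)


def build_pathway_report(
    universe: PathwayUniverse,
    calls: Sequence[KOEnrichment],
    p_floor: float = 1e-300,
) -> list[PathwayEnrichment]:
    """Score every pathway containing at least one enriched KO.

    Rows are sorted by descending ES, ties by pathway id.  Enriched KOs
    that belong to no pathway in the universe are reported with a warning
    (they simply do not contribute anywhere).
    """
    per_pathway: dict[str, list[tuple[str, float]]] = {}
    orphans = []
    for call in calls:
        if not call.enriched:
            continue
        hit = universe.pathways_for_ko(call.ko_id)
        if not hit:
            orphans.append(call.ko_id)
            continue
        for pid in hit:
            per_pathway.setdefault(pid, []).append((call.ko_id, call.p_value))
    if orphans:
        warnings.warn(
            f"{len(orphans)} enriched KO(s) belong to no pathway, "
            f"e.g. {orphans[0]}",
            stacklevel=2,
        )
    report = []
    for pid, kos in per_pathway.items():
        kos.sort()
        pathway = universe[pid]
        es = pathway_enrichment_score(kos, pathway.T, p_floor=p_floor)
        report.append(
            PathwayEnrichment(
                pathway_id=pid,
                name=pathway.name,
                enriched_kos=tuple(kos),
                es=es,
                T=pathway.T,
            )
        )
    report.sort(key=lambda r: (-r.es, r.pathway_id))
    return report


def report_frame(report: Sequence[PathwayEnrichment]) -> pd.DataFrame:
    """Tabular form of the pathway report (columns mirror the published
    pathway table: id, name, score, enriched / total KO counts, KO list)."""
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in report],
            "name": [r.name for r in report],
            "enrichment_score": [r.es for r in report],
            "n_kos_enriched": [r.N for r in report],
            "n_kos_total": [r.T for r in report],
            "enriched_kos": [";".join(ko for ko, _ in r.enriched_kos) for r in report],
        }
    )
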