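"""Read-level ortholog-group annotation tables.

The unit of analysis throughout the pipeline is a *(read, KO)* annotation:
a DNA read that a similarity search assigned to a KEGG Orthology (KO) group,
together with the search e-value and percent identity.  Annotation exports
from servers such as MG-RAST are tab-delimited, sometimes with reads
collapsed into similarity clusters (``aa90_xxx`` identifiers) that must be
re-expanded to their member reads before counting.

This module reads such tables, expands clusters, applies the quality
filters (e-value, percent identity) and produces per-KO count tables — the
inputs of the enrichment stage.
"""

from __future__ import annotations

import csv
import io
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import pandas as pd

__all__ = [
    "TableDialect",
    "AnnotationSet",
    "ClusterMapping",
    "KOCountTable",
    "read_annotation_table",
    "write_annotation_table",
    "expand_clusters",
    "filter_annotations",
    "count_kos",
]

#: canonical column order of the in-memory annotation frame
COLUMNS = ["read_id", "ko_id", "e_value", "pct_identity", "dataset_label"]

Source = Union[str, os.PathLike, io.IOBase]


@dataclass(frozen=True)
class TableDialect:
    """Column layout of a tab-delimited annotation export.

    Columns are given either as 0-based integer positions or, when
    ``has_header`` is true, as header names.  ``pct_identity`` may be
    ``None`` for exports that do not report identity (the identity filter
    is then unavailable for that table).
    """

    read_id: int | str = 0
    ko_id: int | str = 1
    e_value: int | str = 2
    pct_identity: int | str | None = 3
    has_header: bool = False
    comment_char: str = "#"


def _dedupe(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (read_id, ko_id) pairs keeping the smallest
    e-value; ties broken by first occurrence (stable sort)."""
    if frame.empty:
        return frame
    out = (
        frame.sort_values("e_value", kind="stable")
        .drop_duplicates(subset=["read_id", "ko_id"], keep="first")
        .sort_index()
    )
    return out.reset_index(drop=True)


@dataclass
class AnnotationSet:
    """An ordered collection of (read, KO) annotation records.

    Invariants: no two records share the same (read_id, ko_id) pair; a
    read may carry annotations to several distinct KOs.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.frame.columns) != COLUMNS:
            missing = [c for c in COLUMNS if c not in self.frame.columns]
            if missing:
                raise ValueError(f"annotation frame missing columns: {missing}")
            self.frame = self.frame[COLUMNS]
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], provenance: str = ""
    ) -> "AnnotationSet":
        """Build from an iterable of (read_id, ko_id, e_value,
        pct_identity[, dataset_label]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 4:
                rec = rec + ("",)
            rows.append(rec)
        frame = pd.DataFrame(rows, columns=COLUMNS)
        if not frame.empty:
            frame["e_value"] = frame["e_value"].astype(float)
            frame["pct_identity"] = frame["pct_identity"].astype(float)
        return cls(_dedupe(frame), provenance=provenance)

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[tuple]:
        return self.frame.itertuples(index=False, name="AnnotationRecord")

    def validate(self) -> None:
        f = self.frame
        if f.empty:
            return
        if (f["e_value"] < 0).any():
            raise ValueError("negative e-values present")
        ident = f["pct_identity"].dropna()
        if ((ident < 0) | (ident > 100)).any():
            raise ValueError("pct_identity outside [0, 100]")
        if (f["ko_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty KO identifiers present")
        if f.duplicated(subset=["read_id", "ko_id"]).any():
            raise ValueError("duplicate (read_id, ko_id) records present")


@dataclass
class ClusterMapping:
    """Mapping from a similarity-cluster id to its member read ids.

    Invariants: every cluster is non-empty; member sets are disjoint
    across clusters.
    """

    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, reads in self.members.items():
            reads = tuple(reads)
            if not reads:
                raise ValueError(f"cluster {cid!r} has no members")
            overlap = seen.intersection(reads)
            if overlap:
                raise ValueError(
                    f"read(s) {sorted(overlap)[:3]} belong to more than one cluster"
                )
            seen.update(reads)
            self.members[cid] = reads

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self.members

    @classmethod
    def read_tsv(cls, source: Source) -> "ClusterMapping":
        """Read a two-column TSV (cluster_id, read_id), one member per line."""
        members: dict[str, list[str]] = {}
        with _open(source) as handle:
            for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), 1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"line {lineno}: expected 2 columns, got {len(row)}")
                members.setdefault(row[0], []).append(row[1])
        return cls({c: tuple(r) for c, r in members.items()})

    def write_tsv(self, dest: Source) -> None:
        with _open(dest, "w") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            for cid in self.members:
                for read in self.members[cid]:
                    w.writerow([cid, read])


@dataclass
class KOCountTable:
    """Per-KO annotation counts; ``total`` is the table-wide record count."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative counts")
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not equal the sum of counts")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "KOCountTable":
        counts = {k: int(v) for k, v in counts.items()}
        return cls(counts=counts, total=sum(counts.values()))

    def __getitem__(self, ko: str) -> int:
        return self.counts.get(ko, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def write_tsv(self, dest: Source) -> None:
        with _open(dest, "w") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["ko_id", "count"])
            for ko in sorted(self.counts):
                w.writerow([ko, self.counts[ko]])

    @classmethod
    def read_tsv(cls, source: Source) -> "KOCountTable":
        frame = pd.read_csv(source, sep="\t")
        return cls.from_counts(dict(zip(frame["ko_id"], frame["count"])))


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, newline="" if "w" in mode else None)
    # already a file-like object; wrap so `with` does not close it
    class _NoClose:
        def __init__(self, h):
            self.h = h

        def __enter__(self):
            return self.h

        def __exit__(self, *exc):
            return False

    return _NoClose(source)


def read_annotation_table(
    source: Source,
    dialect: TableDialect | None = None,
    dataset_label: str = "",
    on_malformed: str = "warn",
) -> AnnotationSet:
    """Parse a tab-delimited annotation table into an :class:`AnnotationSet`.

    Malformed lines (too few fields, unparsable numbers, out-of-range
    values) are reported with their line numbers — warned about by default,
    or raised when ``on_malformed='error'``.  A missing mandatory column is
    always a hard error naming the column.  Duplicate (read, KO) pairs are
    collapsed keeping the smallest e-value.  Empty input yields an empty
    set, not an error.
    """
    if dialect is None:
        dialect = TableDialect()
    if on_malformed not in ("warn", "error", "ignore"):
        raise ValueError(f"unknown on_malformed policy: {on_malformed!r}")

    colmap: dict[str, int | None] = {}
    rows: list[tuple] = []
    bad: list[tuple[int, str]] = []

    with _open(source) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header_done = not dialect.has_header
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith(dialect.comment_char):
                continue
            if not header_done:
                names = [c.strip() for c in row]
                for attr in ("read_id", "ko_id", "e_value", "pct_identity"):
                    spec = getattr(dialect, attr)
                    if spec is None:
                        colmap[attr] = None
                    elif isinstance(spec, str):
                        if spec not in names:
                            raise ValueError(
                                f"mandatory column {spec!r} ({attr}) not found in header"
                            )
                        colmap[attr] = names.index(spec)
                    else:
                        colmap[attr] = spec
                header_done = True
                continue
            if not colmap:
                for attr in ("read_id", "ko_id", "e_value", "pct_identity"):
                    spec = getattr(dialect, attr)
                    if spec is not None and isinstance(spec, str):
                        raise ValueError(
                            f"column {spec!r} ({attr}) given by name but the "
                            "dialect declares no header"
                        )
                    colmap[attr] = spec
                needed = max(v for v in colmap.values() if v is not None)
                if len(row) <= needed:
                    raise ValueError(
                        f"mandatory column index {needed} absent: first data line "
                        f"has only {len(row)} fields"
                    )
            try:
                read_id = row[colmap["read_id"]].strip()
                ko_id = row[colmap["ko_id"]].strip()
                e_value = float(row[colmap["e_value"]])
                if colmap["pct_identity"] is None:
                    pct = float("nan")
                else:
                    pct = float(row[colmap["pct_identity"]])
            except (IndexError, ValueError) as exc:
                bad.append((lineno, str(exc)))
                continue
            if not ko_id or e_value < 0 or (pct == pct and not 0 <= pct <= 100):
                bad.append((lineno, "field value out of range"))
                continue
            rows.append((read_id, ko_id, e_value, pct, dataset_label))

    if bad:
        msg = "; ".join(f"line {ln}: {why}" for ln, why in bad[:10])
        if len(bad) > 10:
            msg += f"; ... ({len(bad)} malformed lines total)"
        if on_malformed == "error":
            raise ValueError(f"malformed annotation lines: {msg}")
        if on_malformed == "warn":
            warnings.warn(f"skipped malformed annotation lines: {msg}", stacklevel=2)

    frame = pd.DataFrame(rows, columns=COLUMNS)
    return AnnotationSet(_dedupe(frame), provenance=f"parsed {len(rows)} lines")


def write_annotation_table(annos: AnnotationSet, dest: Source) -> None:
    """Write the canonical four-column annotation TSV (with header)."""
    with _open(dest, "w") as handle:
        annos.frame[["read_id", "ko_id", "e_value", "pct_identity"]].to_csv(
            handle, sep="\t", index=False, lineterminator="\n"
        )


#: dialect matching :func:`write_annotation_table` output
CANONICAL_DIALECT = TableDialect(
    read_id="read_id",
    ko_id="ko_id",
    e_value="e_value",
    pct_identity="pct_identity",
    has_header=True,
)


def expand_clusters(
    annos: AnnotationSet,
    mapping: ClusterMapping,
    cluster_prefix: str = "aa90_",
    missing: str = "warn",
) -> AnnotationSet:
    """Replace cluster-level records by one record per member read.

    Records whose read_id is a known cluster id are fanned out to their
    member reads, copying ko_id / e-value / identity.  Other records pass
    through unchanged.  A record whose read_id *looks* like a cluster
    (``cluster_prefix``) but is absent from the mapping is kept with a
    warning by default; ``missing='error'`` raises instead.
    """
    if missing not in ("warn", "error", "ignore"):
        raise ValueError(f"unknown missing-cluster policy: {missing!r}")
    frame = annos.frame
    if frame.empty or not mapping.members:
        return AnnotationSet(frame.copy(), provenance=annos.provenance)

    is_cluster = frame["read_id"].isin(mapping.members.keys())
    if missing != "ignore":
        orphan = frame.loc[
            ~is_cluster & frame["read_id"].str.startswith(cluster_prefix), "read_id"
        ]
        if len(orphan):
            msg = (
                f"{len(orphan)} cluster-style record(s) absent from the mapping, "
                f"e.g. {orphan.iloc[0]!r}"
            )
            if missing == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; kept as-is", stacklevel=2)

    plain = frame[~is_cluster]
    clustered = frame[is_cluster].copy()
    clustered["read_id"] = clustered["read_id"].map(
        {k: list(v) for k, v in mapping.members.items()}
    )
    expanded = clustered.explode("read_id", ignore_index=True)
    out = pd.concat([plain, expanded], ignore_index=True)
    return AnnotationSet(
        _dedupe(out), provenance=annos.provenance + " +cluster-expanded"
    )


def filter_annotations(
    annos: AnnotationSet,
    max_e_value: float,
    min_identity: float | None = None,
) -> AnnotationSet:
    """Keep records with e_value < max_e_value and, when an identity
    threshold is given, pct_identity > min_identity (strict inequalities).

    Records without an identity value fail the identity filter when one is
    requested.
    """
    if max_e_value <= 0:
        raise ValueError("max_e_value must be positive")
    frame = annos.frame
    keep = frame["e_value"] < max_e_value
    if min_identity is not None:
        keep &= frame["pct_identity"] > min_identity
    return AnnotationSet(
        frame[keep].reset_index(drop=True), provenance=annos.provenance + " +filtered"
    )


def count_kos(annos: AnnotationSet, mode: str = "per_ko") -> KOCountTable:
    """Count KO appearances across reads.

    ``per_ko`` (default): each distinct (read, KO) record counts once, so a
    read annotated to two different KOs contributes to both.  ``best_hit``:
    each read contributes only its single smallest-e-value record.
    """
    frame = annos.frame
    if mode == "best_hit":
        frame = (
            frame.sort_values("e_value", kind="stable")
            .drop_duplicates(subset=["read_id"], keep="first")
        )
    elif mode != "per_ko":
        raise ValueError(f"unknown counting mode: {mode!r}")
    counts = frame["ko_id"].value_counts().to_dict()
    return KOCountTable.from_counts(counts)
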