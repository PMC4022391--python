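"""Over-representation tests for ortholog groups in viral metagenomes.

Two sampling designs are supported, matching the two kinds of comparison a
marine viral metagenome allows:

* **superset** — the viral read set is a literal subset of the reference
  metagenome (e.g. viral-classified scaffolds drawn from a larger survey).
  Enrichment of a KO is the hypergeometric upper tail P(X >= k) of drawing
  k reads of that KO in n viral annotations, given K of N reference
  annotations carry it.
* **paired** — virome and microbiome are two independent samples from the
  same site (viral-size vs microbial-size filter fractions).  Enrichment
  is the one-sided Fisher exact test on the 2x2 contingency table.

KOs with p below ``alpha`` (default 1e-4, uncorrected) are flagged
enriched; Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import KOCountTable, _open

__all__ = [
    "KOEnrichment",
    "hypergeom_pmf",
    "hypergeom_upper_tail",
    "hypergeom_upper_tail_exact",
    "fisher_exact_greater",
    "call_enriched_kos",
    "adjust_pvalues",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
]


@dataclass(frozen=True)
class KOEnrichment:
    """Per-KO 2x2 counts and enrichment call.

    In the superset design k/K are subset/reference counts of the KO and
    n/N the subset/reference annotation totals (k <= K, n <= N).  In the
    paired design the same fields hold the virome (k, n) and microbiome
    (K, N) counts with no nesting constraint.
    """

    ko_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    enriched: bool
    alpha: float
    p_adjusted: float | None = None


def _check_hypergeom(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (K <= N and n <= N):
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k < n - (N - K):
        raise ValueError(
            f"impossible table: k={k} < n - (N - K) = {n - (N - K)}"
        )


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Point mass P(X = k) for X ~ Hypergeom(N items, K successes, n draws)."""
    _check_hypergeom(k, K, n, N)
    return float(stats.hypergeom.pmf(k, N, K, n))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N items, K successes, n draws).

    Evaluated through scipy's log-gamma survival function; agrees with the
    exact rational tail to ~1e-13 absolute on small inputs.
    """
    _check_hypergeom(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational P(X >= k); integer arithmetic, intended for small N."""
    _check_hypergeom(k, K, n, N)
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    )
    return Fraction(num, math.comb(N, n))


def fisher_exact_greater(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided (greater in sample 1) Fisher exact p-value for the 2x2
    table [[k1, n1-k1], [k2, n2-k2]].

    Equivalent to the hypergeometric upper tail conditioned on the table
    margins.
    """
    if not (0 <= k1 <= n1):
        raise ValueError(f"need 0 <= k1 <= n1; got k1={k1}, n1={n1}")
    if not (0 <= k2 <= n2):
        raise ValueError(f"need 0 <= k2 <= n2; got k2={k2}, n2={n2}")
    if n1 + n2 == 0:
        raise ValueError("empty table")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def call_enriched_kos(
    subset: KOCountTable,
    reference: KOCountTable,
    design: str = "superset",
    alpha: float = 1e-4,
) -> list[KOEnrichment]:
    """Call KOs over-represented in ``subset`` relative to ``reference``.

    One result per KO present in the tested (subset) table, sorted by
    ascending p-value then KO id.  ``enriched`` is ``p < alpha``
    (uncorrected; see :func:`adjust_pvalues`).
    """
    if design not in ("superset", "paired"):
        raise ValueError(f"unknown design: {design!r}")
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must be in [0, 1]")
    n = subset.total
    N = reference.total
    kos = sorted(subset.counts)
    if not kos:
        return []
    k = np.array([subset.counts[ko] for ko in kos], dtype=np.int64)

    if design == "superset":
        if n > N:
            raise ValueError(f"subset total {n} exceeds reference total {N}")
        K = np.empty(len(kos), dtype=np.int64)
        for i, ko in enumerate(kos):
            Kv = reference[ko]
            if k[i] > Kv:
                raise ValueError(
                    f"superset design violated for {ko}: subset count {k[i]} "
                    f"exceeds reference count {Kv}"
                )
            K[i] = Kv
        pvals = stats.hypergeom.sf(k - 1, N, K, n)
        pvals = np.clip(pvals, 0.0, 1.0)
    else:
        K = np.array([reference[ko] for ko in kos], dtype=np.int64)
        pvals = np.array(
            [fisher_exact_greater(int(ki), n, int(Ki), N) for ki, Ki in zip(k, K)]
        )

    results = [
        KOEnrichment(
            ko_id=ko,
            k=int(ki),
            K=int(Ki),
            n=n,
            N=N,
            p_value=float(p),
            enriched=bool(p < alpha),
            alpha=alpha,
        )
        for ko, ki, Ki, p in zip(kos, k, K, pvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.ko_id))
    return results


def adjust_pvalues(
    results: Sequence[KOEnrichment], method: str = "none"
) -> list[KOEnrichment]:
    """Optionally apply multiple-testing correction.

    ``none`` returns the input unchanged (the default analysis applies a
    raw threshold).  ``benjamini-hochberg`` computes BH step-up adjusted
    p-values and re-derives the enriched flags from them.
    """
    if method == "none":
        return list(results)
    if method != "benjamini-hochberg":
        raise ValueError(f"unknown adjustment method: {method!r}")
    if not results:
        return []
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return [
        replace(r, p_adjusted=float(a), enriched=bool(a < r.alpha))
        for r, a in zip(results, adjusted)
    ]


_ENRICH_COLUMNS = ["ko_id", "k", "K", "n", "N", "p_value", "enriched"]


def write_enrichment_tsv(results: Sequence[KOEnrichment], dest) -> None:
    """Write the per-KO enrichment table (with adjusted column if set)."""
    has_adj = any(r.p_adjusted is not None for r in results)
    cols = _ENRICH_COLUMNS + (["p_adjusted"] if has_adj else [])
    with _open(dest, "w") as handle:
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in results:
            row = [r.ko_id, r.k, r.K, r.n, r.N, repr(r.p_value), int(r.enriched)]
            if has_adj:
                row.append("" if r.p_adjusted is None else repr(r.p_adjusted))
            w.writerow(row)


def read_enrichment_tsv(source, alpha: float = 1e-4) -> list[KOEnrichment]:
    frame = pd.read_csv(source, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            KOEnrichment(
                ko_id=str(row.ko_id),
                k=int(row.k),
                K=int(row.K),
                n=int(row.n),
                N=int(row.N),
                p_value=float(row.p_value),
                enriched=bool(row.enriched),
                alpha=alpha,
                p_adjusted=float(row.p_adjusted)
                if hasattr(row, "p_adjusted") and row.p_adjusted == row.p_adjusted
                else None,
            )
        )
    return out
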