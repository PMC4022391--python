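"""The global metabolism network and its analyses.

Each metabolic pathway is a node; an undirected, unweighted edge joins
pathways A and B whenever a product compound of one is a substrate of the
other.  On this graph the module runs the analyses that characterise where
viral-enriched pathways sit:

* degree ranking and the exact minimal-hypergeometric (mHG) test for
  over-representation of enriched pathways among the best-connected nodes;
* a Mann-Whitney comparison of the degree distributions of enriched vs
  non-enriched pathways;
* breadth-first distance shells around a set of target pathways (e.g. the
  purine and pyrimidine metabolism nodes), per-shell hypergeometric
  enrichment, and a t-test comparison of the distance distributions.

The mHG statistic of a ranked binary membership vector is the minimum,
over all prefix lengths l, of the hypergeometric upper tail of seeing that
many members in the top l.  Because the minimisation optimises over the
cutoff, the statistic itself is not a p-value; the exact p-value is the
probability, under uniform random permutations of the vector, of reaching
an equally small or smaller minimum.  It is computed here by exact
lattice-path counting in rational arithmetic, so no sampling error or
floating-point threshold enters the result.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .annotations import _open
from .enrichment import hypergeom_upper_tail
from .pathways import PathwayUniverse

__all__ = [
    "MetabolismNetwork",
    "RankedEnrichmentResult",
    "DistanceShellResult",
    "build_network",
    "rank_by_degree",
    "mhg_statistic_and_pvalue",
    "mhg_pvalue_sampled",
    "compare_degree_distributions",
    "distance_shells",
    "shell_enrichment",
    "compare_distance_distributions",
    "export_network",
    "import_network",
]


@dataclass
class MetabolismNetwork:
    """Pathway-level graph with the subset of enriched pathway nodes."""

    graph: nx.Graph
    enriched: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.enriched = frozenset(self.enriched)
        stray = self.enriched - set(self.graph.nodes)
        if stray:
            raise ValueError(f"enriched nodes absent from the graph: {sorted(stray)[:3]}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    universe: PathwayUniverse,
    enriched: Iterable[str] = (),
    exclude_compounds: Iterable[str] = (),
) -> MetabolismNetwork:
    """Connect pathways that share a produced/consumed compound.

    An undirected edge {A, B} (A != B) exists iff products(A) meets
    substrates(B) or products(B) meets substrates(A), after removing any
    compounds on the exclusion list (e.g. currency metabolites; empty by
    default).
    """
    excluded = frozenset(exclude_compounds)
    graph = nx.Graph()
    producers: dict[str, set[str]] = {}
    for p in universe:
        graph.add_node(p.pathway_id, name=p.name)
        for c in p.products - excluded:
            producers.setdefault(c, set()).add(p.pathway_id)
    for p in universe:
        for c in p.substrates - excluded:
            for other in producers.get(c, ()):
                if other != p.pathway_id:
                    graph.add_edge(other, p.pathway_id)
    enriched = frozenset(enriched) & set(graph.nodes)
    return MetabolismNetwork(graph=graph, enriched=enriched)


def rank_by_degree(net: MetabolismNetwork) -> tuple[list[str], np.ndarray]:
    """Sort nodes by descending degree (ties broken by node id) and return
    the ordered node list plus the 0/1 enriched-membership vector."""
    order = sorted(net.graph.nodes, key=lambda v: (-net.graph.degree(v), v))
    vector = np.array([1 if v in net.enriched else 0 for v in order], dtype=np.int8)
    return order, vector


# ---------------------------------------------------------------------------
# minimal hypergeometric (mHG)


@dataclass(frozen=True)
class RankedEnrichmentResult:
    """mHG outcome: the minimised prefix tail, the prefix length attaining
    it, and the exact permutation p-value."""

    mhg_statistic: float
    cutoff_index: int
    p_value: float


def _exact_tails(L: int, B: int) -> list[list[Fraction]]:
    """tails[l][b] = P(X >= b) for X ~ Hypergeom(L, B, l), exact."""
    comb = math.comb
    tails: list[list[Fraction]] = []
    for l in range(L + 1):
        denom = comb(L, l)
        row = []
        lo = max(0, l - (L - B))
        hi = min(l, B)
        # suffix sums of the pmf numerators
        pmf = [comb(B, b) * comb(L - B, l - b) if lo <= b <= hi else 0
               for b in range(hi + 1)]
        suffix = [0] * (hi + 2)
        for b in range(hi, -1, -1):
            suffix[b] = suffix[b + 1] + pmf[b]
        for b in range(hi + 1):
            row.append(Fraction(suffix[b], denom))
        tails.append(row)
    return tails


def mhg_statistic_and_pvalue(vector: Sequence[int]) -> RankedEnrichmentResult:
    """Exact mHG statistic and p-value of a ranked 0/1 membership vector.

    The statistic minimises the hypergeometric upper tail over all prefix
    lengths 1..L; the p-value counts, by dynamic programming over lattice
    paths in exact rational arithmetic, the fraction of the C(L, B)
    distinct orderings of the vector whose minimum is at least as small.
    """
    vec = [int(v) for v in vector]
    if len(vec) < 1:
        raise ValueError("vector must be non-empty")
    if any(v not in (0, 1) for v in vec):
        raise ValueError("vector must be binary")
    L = len(vec)
    B = sum(vec)
    if B == 0:
        raise ValueError("vector contains no ones; mHG is undefined")

    tails = _exact_tails(L, B)
    # statistic along the observed vector
    stat = Fraction(1)
    cutoff = 1
    b = 0
    for l in range(1, L + 1):
        b += vec[l - 1]
        t = tails[l][b]
        if t < stat:
            stat = t
            cutoff = l

    # exact p-value: count paths (orderings) never entering a cell with
    # tail <= stat; p = 1 - good_paths / C(L, B)
    W = L - B
    # ways[b] = number of paths reaching (l, b) avoiding rejected cells
    ways = [0] * (B + 1)
    ways[0] = 1
    if tails[0][0] <= stat:  # only possible when stat == 1
        ways[0] = 0
    for l in range(1, L + 1):
        lo = max(0, l - W)
        hi = min(l, B)
        for bb in range(hi, lo - 1, -1):
            total = 0
            if bb <= l - 1 and bb <= B:  # arrive via a zero
                total += ways[bb]
            if bb - 1 >= 0 and bb - 1 <= l - 1:  # arrive via a one
                total += ways[bb - 1]
            if bb < len(tails[l]) and tails[l][bb] <= stat:
                total = 0  # rejected cell: path already attained the minimum
            ways[bb] = total
        for bb in range(0, lo):
            ways[bb] = 0
    good = ways[B]
    p = 1 - Fraction(good, math.comb(L, B))
    return RankedEnrichmentResult(
        mhg_statistic=float(stat), cutoff_index=cutoff, p_value=float(p)
    )


def mhg_pvalue_sampled(
    vector: Sequence[int], n_permutations: int = 10000, rng=None
) -> float:
    """Permutation-sampling estimate of the mHG p-value (validation aid)."""
    rng = np.random.default_rng(rng)
    vec = np.asarray(vector, dtype=np.int8)
    observed = mhg_statistic_and_pvalue(vec).mhg_statistic
    hits = 0
    work = vec.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if mhg_statistic_and_pvalue(work).mhg_statistic <= observed + 1e-15:
            hits += 1
    return hits / n_permutations


# ---------------------------------------------------------------------------
# degree and distance comparisons


def compare_degree_distributions(net: MetabolismNetwork) -> dict:
    """Two-sided Mann-Whitney rank-sum comparison of node degrees between
    enriched and non-enriched pathways.

    The reported U statistic follows the scipy convention: the number of
    (enriched, other) pairs in which the enriched degree is larger, ties
    counting one half.
    """
    enriched = sorted(net.enriched)
    other = sorted(set(net.graph.nodes) - net.enriched)
    if not enriched or not other:
        raise ValueError("both groups must be non-empty")
    deg_e = [net.graph.degree(v) for v in enriched]
    deg_o = [net.graph.degree(v) for v in other]
    res = stats.mannwhitneyu(deg_e, deg_o, alternative="two-sided")
    return {
        "mean_enriched": float(np.mean(deg_e)),
        "mean_other": float(np.mean(deg_o)),
        "u_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_enriched": len(deg_e),
        "n_other": len(deg_o),
    }


@dataclass
class DistanceShellResult:
    """BFS distances from a target pathway set.

    ``distances`` maps each reachable non-target node to its shortest-path
    distance to the nearest target (``mode='merged'``) or to the farthest
    target (``mode='max'``); ``shells`` groups those nodes by distance.
    Target nodes sit at distance 0 and are excluded from shells, as are
    unreachable nodes.
    """

    targets: frozenset[str]
    distances: dict[str, int]
    shells: dict[int, set[str]]
    unreachable: frozenset[str]
    mode: str = "merged"


def distance_shells(
    net: MetabolismNetwork, targets: Iterable[str], mode: str = "merged"
) -> DistanceShellResult:
    """Assign every pathway its path-length shell relative to ``targets``.

    ``merged`` treats the target set as one BFS source (distance to the
    nearest target); ``max`` requires reachability from every target and
    uses the largest per-target distance.
    """
    targets = frozenset(targets)
    if not targets:
        raise ValueError("target set is empty")
    stray = targets - set(net.graph.nodes)
    if stray:
        raise ValueError(f"targets absent from the network: {sorted(stray)}")
    if mode not in ("merged", "max"):
        raise ValueError(f"unknown distance mode: {mode!r}")

    if mode == "merged":
        dist: dict[str, int] = {}
        for d, layer in enumerate(nx.bfs_layers(net.graph, sorted(targets))):
            for v in layer:
                dist[v] = d
    else:
        per_target = [
            nx.single_source_shortest_path_length(net.graph, t) for t in sorted(targets)
        ]
        dist = {}
        for v in net.graph.nodes:
            if all(v in dt for dt in per_target):
                dist[v] = max(dt[v] for dt in per_target)

    distances = {v: d for v, d in dist.items() if v not in targets}
    unreachable = frozenset(set(net.graph.nodes) - targets - set(distances))
    shells: dict[int, set[str]] = {}
    for v, d in distances.items():
        shells.setdefault(d, set()).add(v)
    return DistanceShellResult(
        targets=targets,
        distances=distances,
        shells={d: shells[d] for d in sorted(shells)},
        unreachable=unreachable,
        mode=mode,
    )


def shell_enrichment(
    shells: DistanceShellResult, enriched: Iterable[str]
) -> dict[int, dict]:
    """Hypergeometric over-representation of enriched pathways per shell.

    For each distance d: k enriched nodes out of n in the shell, against K
    enriched among all N shell-assigned (reachable, non-target) nodes.
    """
    enriched = frozenset(enriched)
    assigned = set(shells.distances)
    N = len(assigned)
    K = len(assigned & enriched)
    out = {}
    for d, members in shells.shells.items():
        n = len(members)
        k = len(members & enriched)
        p = hypergeom_upper_tail(k, K, n, N) if N else 1.0
        out[d] = {"n_pathways": n, "n_enriched": k, "p_value": p}
    return out


def compare_distance_distributions(
    shells: DistanceShellResult,
    enriched: Iterable[str],
    equal_var: bool = False,
) -> dict:
    """Two-sample t-test on per-node distances of enriched vs non-enriched
    pathways (Welch by default; ``equal_var=True`` pools variances)."""
    enriched = frozenset(enriched)
    d_e = [d for v, d in shells.distances.items() if v in enriched]
    d_o = [d for v, d in shells.distances.items() if v not in enriched]
    if len(d_e) < 2 or len(d_o) < 2:
        raise ValueError("each group needs at least two distance values")
    res = stats.ttest_ind(d_e, d_o, equal_var=equal_var)
    return {
        "mean_enriched": float(np.mean(d_e)),
        "mean_other": float(np.mean(d_o)),
        "t_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_enriched": len(d_e),
        "n_other": len(d_o),
        "equal_var": equal_var,
    }


# ---------------------------------------------------------------------------
# export


def export_network(net: MetabolismNetwork, path, fmt: str = "graphml") -> None:
    """Write the network with its enriched-node attribute.

    ``graphml`` is lossless in one file.  ``edgelist`` writes a two-column
    edge TSV plus a companion ``<path>.nodes.tsv`` carrying every node and
    its enriched flag (so isolated nodes round-trip too).
    """
    if fmt == "graphml":
        g = net.graph.copy()
        for v in g.nodes:
            g.nodes[v]["enriched"] = v in net.enriched
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with _open(path, "w") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["node_a", "node_b"])
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                w.writerow([a, b])
        with _open(f"{path}.nodes.tsv", "w") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["node_id", "enriched"])
            for v in sorted(net.graph.nodes):
                w.writerow([v, int(v in net.enriched)])
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def import_network(path, fmt: str = "graphml") -> MetabolismNetwork:
    """Re-read a network written by :func:`export_network`."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
        enriched = frozenset(v for v, d in g.nodes(data=True) if d.get("enriched"))
        for v in g.nodes:
            g.nodes[v].pop("enriched", None)
        return MetabolismNetwork(graph=g, enriched=enriched)
    if fmt == "edgelist":
        g = nx.Graph()
        enriched = set()
        with _open(f"{path}.nodes.tsv") as handle:
            reader = csv.reader(handle, delimiter="\t")
            next(reader)
            for node, flag in reader:
                g.add_node(node)
                if int(flag):
                    enriched.add(node)
        with _open(path) as handle:
            reader = csv.reader(handle, delimiter="\t")
            next(reader)
            for a, b in reader:
                g.add_edge(a, b)
        return MetabolismNetwork(graph=g, enriched=frozenset(enriched))
    raise ValueError(f"unknown import format: {fmt!r}")
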