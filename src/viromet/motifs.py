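"""Metabolic motif mining in per-pathway reaction graphs.

A pathway's reaction graph has compounds as nodes and reactions as directed
edges (substrate -> product), each labelled with the KO group(s) whose
enzymes promote it.  A *metabolic motif* is a chain of consecutive
reactions (product of one is the substrate of the next) of length >= 4 in
which at least three reactions are promoted by viral-enriched KOs and at
most one is not.  Motifs capture stretches of a pathway whose successive
steps are coordinately enhanced in the viral gene pool.

Chain significance follows a successive-Bernoulli scheme: with p the
fraction of the pathway's reactions promoted by an enriched KO, each
transition into a compound c contributes the binomial point mass
C(n, y) p^y (1-p)^(n-y), where n is the number of reactions containing c
(excluding the reaction the chain arrived by) and y how many of those are
enriched; the motif p-value is the product over transitions.  An
upper-tail variant (P(Y >= y) per transition) is available, as is the
option to score the first reaction's own compound.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotations import _open

__all__ = [
    "Reaction",
    "ReactionGraph",
    "Motif",
    "load_reaction_graph",
    "load_reaction_graph_kgml",
    "find_motifs",
    "motif_pvalue",
    "score_motifs",
    "motif_report_frame",
]


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrate: str
    product: str
    kos: frozenset[str]
    enriched: bool


@dataclass
class ReactionGraph:
    """Compound/reaction graph of one pathway with enrichment flags."""

    pathway_id: str
    compounds: frozenset[str]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for c in (r.substrate, r.product):
                if c not in self.compounds:
                    raise ValueError(
                        f"reaction {r.reaction_id} references undeclared compound {c!r}"
                    )
        self._incident: dict[str, list[Reaction]] = {}
        for r in self.reactions:
            self._incident.setdefault(r.substrate, []).append(r)
            if r.product != r.substrate:
                self._incident.setdefault(r.product, []).append(r)

    def __len__(self) -> int:
        return len(self.reactions)

    def incident(self, compound: str) -> list[Reaction]:
        """Reactions having ``compound`` as substrate or product."""
        return list(self._incident.get(compound, ()))

    @property
    def enriched_fraction(self) -> float:
        if not self.reactions:
            raise ValueError(f"pathway {self.pathway_id} has no reactions")
        return sum(r.enriched for r in self.reactions) / len(self.reactions)


def _resolve(kos: Iterable[str], enriched_kos: frozenset[str]) -> bool:
    return bool(frozenset(kos) & enriched_kos)


def load_reaction_graph(
    source,
    enriched_kos: Iterable[str],
    pathway_id: str = "",
) -> ReactionGraph:
    """Read a reaction TSV: reaction_id, substrate, product, KO list
    (semicolon-separated), with a header line.

    An optional ``# compounds: c1;c2;...`` comment line declares the
    compound set; reactions referencing compounds outside it are a hard
    error.  Without it the compound set is inferred from the reactions.
    A ``# pathway: xxx`` comment line sets the pathway id.
    """
    enriched_kos = frozenset(enriched_kos)
    declared: frozenset[str] | None = None
    reactions = []
    with _open(source) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row:
                continue
            if row[0].startswith("#"):
                text = "\t".join(row)[1:].strip()
                if text.startswith("compounds:"):
                    declared = frozenset(
                        c for c in text.split(":", 1)[1].strip().split(";") if c
                    )
                elif text.startswith("pathway:"):
                    pathway_id = pathway_id or text.split(":", 1)[1].strip()
                continue
            if row[0] == "reaction_id":
                continue
            if len(row) < 4:
                raise ValueError(f"expected 4 columns, got {len(row)}: {row}")
            kos = frozenset(k for k in row[3].split(";") if k)
            reactions.append(
                Reaction(
                    reaction_id=row[0],
                    substrate=row[1],
                    product=row[2],
                    kos=kos,
                    enriched=_resolve(kos, enriched_kos),
                )
            )
    inferred = frozenset(
        c for r in reactions for c in (r.substrate, r.product)
    )
    compounds = declared if declared is not None else inferred
    return ReactionGraph(
        pathway_id=pathway_id, compounds=compounds, reactions=tuple(reactions)
    )


def write_reaction_graph(graph: ReactionGraph, dest) -> None:
    with _open(dest, "w") as handle:
        handle.write(f"# pathway: {graph.pathway_id}\n")
        handle.write("# compounds: " + ";".join(sorted(graph.compounds)) + "\n")
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(["reaction_id", "substrate", "product", "kos"])
        for r in graph.reactions:
            w.writerow([r.reaction_id, r.substrate, r.product, ";".join(sorted(r.kos))])


def load_reaction_graph_kgml(source, enriched_kos: Iterable[str]) -> ReactionGraph:
    """Read a KGML (KEGG Markup Language) pathway document.

    Each ``<reaction>`` element yields one Reaction per substrate/product
    pair, labelled with the KOs of the ortholog entries that declare the
    reaction.  Reversible reactions are stored in their written direction;
    use the traversal flag of :func:`find_motifs` to walk them backwards.
    """
    from lxml import etree

    enriched_kos = frozenset(enriched_kos)
    if hasattr(source, "read"):
        tree = etree.parse(source)
    else:
        tree = etree.parse(str(source))
    root = tree.getroot()
    pathway_id = root.get("name", "").replace("path:", "")

    # reaction name -> KOs from ortholog entries
    rxn_kos: dict[str, set[str]] = {}
    for entry in root.findall("entry"):
        if entry.get("type") != "ortholog":
            continue
        kos = {n.replace("ko:", "") for n in entry.get("name", "").split()}
        for rname in (entry.get("reaction") or "").split():
            rxn_kos.setdefault(rname, set()).update(kos)

    reactions = []
    compounds: set[str] = set()
    for rxn in root.findall("reaction"):
        rname = rxn.get("name", "")
        kos = frozenset(rxn_kos.get(rname, set()))
        subs = [s.get("name", "").replace("cpd:", "") for s in rxn.findall("substrate")]
        prods = [p.get("name", "").replace("cpd:", "") for p in rxn.findall("product")]
        compounds.update(subs)
        compounds.update(prods)
        idx = 0
        for s in subs:
            for p in prods:
                rid = rname.replace("rn:", "")
                if len(subs) * len(prods) > 1:
                    rid = f"{rid}.{idx}"
                    idx += 1
                reactions.append(
                    Reaction(
                        reaction_id=rid,
                        substrate=s,
                        product=p,
                        kos=kos,
                        enriched=_resolve(kos, enriched_kos),
                    )
                )
    return ReactionGraph(
        pathway_id=pathway_id,
        compounds=frozenset(compounds),
        reactions=tuple(reactions),
    )


# ---------------------------------------------------------------------------
# motif search


@dataclass(frozen=True)
class Motif:
    """An ordered chain of consecutive reactions.

    ``steps`` records (reaction_id, walked_in_reverse) pairs; consecutive
    steps share a compound (the out-compound of one is the in-compound of
    the next).  ``terms`` holds the per-transition scoring detail
    (compound, n, y, term) once the motif has been scored.
    """

    pathway_id: str
    steps: tuple[tuple[str, bool], ...]
    n_enriched: int
    n_nonenriched: int
    p_value: float | None = None
    terms: tuple[tuple[str, int, int, float], ...] | None = None

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.steps)


def _step_ends(r: Reaction, rev: bool) -> tuple[str, str]:
    return (r.product, r.substrate) if rev else (r.substrate, r.product)


def find_motifs(
    graph: ReactionGraph,
    min_len: int = 4,
    min_enriched: int = 3,
    max_nonenriched: int = 1,
    direction: str = "forward",
    maximal: bool = True,
) -> list[Motif]:
    """Enumerate reaction chains satisfying the motif constraints.

    A chain is *simple* (no reaction used twice) and never carries more
    than ``max_nonenriched`` non-enriched reactions.  With ``maximal``
    (default) only chains that cannot be extended at either end without
    breaking a constraint are reported; ``maximal=False`` reports every
    qualifying sub-chain.  ``direction='both'`` also walks reactions
    against their written direction.  Results are ordered by first
    reaction id, then length, then the full id tuple.
    """
    if min_len < min_enriched:
        raise ValueError("min_len must be >= min_enriched")
    if min(min_len, min_enriched, max_nonenriched) < 0:
        raise ValueError("thresholds must be non-negative")
    if direction not in ("forward", "both"):
        raise ValueError(f"unknown direction: {direction!r}")

    by_id = {r.reaction_id: r for r in graph.reactions}
    orientations = [False] if direction == "forward" else [False, True]
    # out-compound -> possible next (reaction, rev) steps
    successors: dict[str, list[tuple[str, bool]]] = {}
    predecessors: dict[str, list[tuple[str, bool]]] = {}
    for r in graph.reactions:
        for rev in orientations:
            inc, outc = _step_ends(r, rev)
            successors.setdefault(inc, []).append((r.reaction_id, rev))
            predecessors.setdefault(outc, []).append((r.reaction_id, rev))

    def nonenr(rid: str) -> int:
        return 0 if by_id[rid].enriched else 1

    found: dict[tuple, Motif] = {}

    def qualifies(chain: list[tuple[str, bool]], bad: int) -> bool:
        if len(chain) < min_len or bad > max_nonenriched:
            return False
        n_enr = sum(1 for rid, _ in chain if by_id[rid].enriched)
        return n_enr >= min_enriched

    def extendable(chain: list[tuple[str, bool]], bad: int, at_front: bool) -> bool:
        used = {rid for rid, _ in chain}
        if at_front:
            inc = _step_ends(by_id[chain[0][0]], chain[0][1])[0]
            options = predecessors.get(inc, ())
        else:
            outc = _step_ends(by_id[chain[-1][0]], chain[-1][1])[1]
            options = successors.get(outc, ())
        for rid, rev in options:
            if rid in used:
                continue
            if bad + nonenr(rid) <= max_nonenriched:
                return True
        return False

    def record(chain: list[tuple[str, bool]], bad: int) -> None:
        if not qualifies(chain, bad):
            return
        if maximal and (
            extendable(chain, bad, at_front=True)
            or extendable(chain, bad, at_front=False)
        ):
            return
        key = tuple(chain)
        if key not in found:
            n_enr = sum(1 for rid, _ in chain if by_id[rid].enriched)
            found[key] = Motif(
                pathway_id=graph.pathway_id,
                steps=key,
                n_enriched=n_enr,
                n_nonenriched=len(chain) - n_enr,
            )

    def dfs(chain: list[tuple[str, bool]], used: set[str], bad: int) -> None:
        record(chain, bad)
        outc = _step_ends(by_id[chain[-1][0]], chain[-1][1])[1]
        for rid, rev in successors.get(outc, ()):
            if rid in used:
                continue
            nb = bad + nonenr(rid)
            if nb > max_nonenriched:
                continue
            chain.append((rid, rev))
            used.add(rid)
            dfs(chain, used, nb)
            used.remove(rid)
            chain.pop()

    for r in graph.reactions:
        for rev in orientations:
            b = nonenr(r.reaction_id)
            if b > max_nonenriched:
                continue
            dfs([(r.reaction_id, rev)], {r.reaction_id}, b)

    motifs = list(found.values())
    motifs.sort(key=lambda m: (m.steps[0][0], len(m), m.steps))
    return motifs


def motif_pvalue(
    motif: Motif,
    graph: ReactionGraph,
    mode: str = "pmf",
    include_first: bool = False,
) -> tuple[float, tuple[tuple[str, int, int, float], ...]]:
    """Score a motif by the successive-Bernoulli chain probability.

    Returns the product p-value and the per-transition detail
    (compound, n, y, term).  ``mode='pmf'`` uses the binomial point mass
    at each transition, ``mode='tail'`` the upper tail P(Y >= y).  With
    ``include_first`` the first reaction's in-compound also contributes a
    term, computed over all reactions at that compound (nothing to
    exclude).
    """
    if mode not in ("pmf", "tail"):
        raise ValueError(f"unknown scoring mode: {mode!r}")
    p = graph.enriched_fraction  # raises on an empty pathway
    by_id = {r.reaction_id: r for r in graph.reactions}

    terms: list[tuple[str, int, int, float]] = []
    prev: Reaction | None = None
    for i, (rid, rev) in enumerate(motif.steps):
        r = by_id[rid]
        inc, _ = _step_ends(r, rev)
        if i == 0 and not include_first:
            prev = r
            continue
        pool = [x for x in graph.incident(inc) if prev is None or x is not prev]
        n = len(pool)
        y = sum(1 for x in pool if x.enriched)
        if mode == "pmf":
            term = float(stats.binom.pmf(y, n, p))
        else:
            term = float(stats.binom.sf(y - 1, n, p)) if y > 0 else 1.0
        terms.append((inc, n, y, term))
        prev = r
    p_value = 1.0
    for _, _, _, t in terms:
        p_value *= t
    return p_value, tuple(terms)


def score_motifs(
    motifs: Sequence[Motif],
    graph: ReactionGraph,
    mode: str = "pmf",
    include_first: bool = False,
) -> list[Motif]:
    """Return copies of ``motifs`` with p_value and terms filled in."""
    out = []
    for m in motifs:
        p, terms = motif_pvalue(m, graph, mode=mode, include_first=include_first)
        out.append(replace(m, p_value=p, terms=terms))
    return out


def motif_report_frame(motifs: Sequence[Motif], alpha: float = 0.05) -> pd.DataFrame:
    """Tabular motif report; ``significant`` only marks motifs below
    ``alpha``, all motifs are listed regardless."""
    return pd.DataFrame(
        {
            "pathway_id": [m.pathway_id for m in motifs],
            "reactions": [
                ";".join(
                    rid + ("(rev)" if rev else "") for rid, rev in m.steps
                )
                for m in motifs
            ],
            "length": [len(m) for m in motifs],
            "n_enriched": [m.n_enriched for m in motifs],
            "n_nonenriched": [m.n_nonenriched for m in motifs],
            "p_value": [m.p_value for m in motifs],
            "significant": [
                bool(m.p_value is not None and m.p_value < alpha) for m in motifs
            ],
        }
    )
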