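"""Knowledge-graph assembly and drug→protein^k→side-effect path search.

Relation triples are merged into a typed directed graph (nodes keyed by
canonical id + entity type; parallel triples increment an edge support
count and accumulate verbs and provenance).  Candidate explanatory
paths run from a drug through k = 1..3 distinct proteins to a side
effect, traversing edges in their asserted direction only.  A final
filter removes paths that end in a treated-condition term (tumor,
cancer, ...) — those describe intended drug effects, not side effects —
and paths whose internal edges carry no directional (increase/decrease)
verb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Callable, Iterable

import networkx as nx

from .lexicon_ner import DRUG, PROTEIN, SIDE_EFFECT
from .relation_extraction import (ALLOWED_TYPE_PAIRS, INCREASE, DECREASE,
                                  RelationTriple)

__all__ = [
    "KnowledgeGraph",
    "KnowledgePath",
    "build_graph",
    "enumerate_paths",
    "filter_significant",
    "DEFAULT_EFFECT_TERMS",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_paths_tsv",
]

Node = tuple[str, str]  # (canonical_id, entity_type)

DEFAULT_EFFECT_TERMS = frozenset(
    {"tumor", "tumour", "cancer", "carcinoma", "neoplasm"})

MAX_DEPTH = 3


class KnowledgeGraph:
    """Typed directed multigraph over drug/protein/side-effect nodes.

    Thin wrapper over a :class:`networkx.DiGraph` whose edges carry a
    ``verbs`` set, a ``polarities`` set, a ``support`` count (number of
    supporting triples) and a ``provenance`` list of (pmid, sentence)
    pairs.  Node names (for display and effect-term filtering) are kept
    as a node attribute.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    def add_triple(self, t: RelationTriple) -> None:
        pair = (t.source.entity_type, t.target.entity_type)
        if pair not in ALLOWED_TYPE_PAIRS:
            raise ValueError(f"disallowed type pair {pair}")
        u: Node = (t.source.canonical_id, t.source.entity_type)
        v: Node = (t.target.canonical_id, t.target.entity_type)
        for node, mention in ((u, t.source), (v, t.target)):
            if node not in self.g:
                self.g.add_node(node, name=mention.surface)
        if self.g.has_edge(u, v):
            data = self.g.edges[u, v]
            data["verbs"].add(t.verb_lemma)
            data["polarities"].add(t.polarity)
            data["support"] += 1
            data["provenance"].append((t.pmid, t.sentence_index))
        else:
            self.g.add_edge(u, v, verbs={t.verb_lemma},
                            polarities={t.polarity}, support=1,
                            provenance=[(t.pmid, t.sentence_index)])

    # -- convenience views -------------------------------------------------
    def nodes_of_type(self, entity_type: str) -> list[Node]:
        return sorted(n for n in self.g.nodes if n[1] == entity_type)

    def edge_data(self, u: Node, v: Node) -> dict:
        return self.g.edges[u, v]

    def node_name(self, n: Node) -> str:
        return self.g.nodes[n].get("name", n[0])

    @property
    def total_support(self) -> int:
        return sum(d["support"] for _, _, d in self.g.edges(data=True))

    def __contains__(self, n: Node) -> bool:
        return n in self.g


@dataclass
class KnowledgePath:
    """A drug, 1–3 bridging proteins and a side effect, with the verb
    set of each connecting edge."""

    drug: Node
    proteins: list[Node]
    side_effect: Node
    edge_verbs: list[frozenset[str]] = field(default_factory=list)
    edge_polarities: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= MAX_DEPTH:
            raise ValueError("path depth must be 1..3")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("proteins on a path must be distinct")

    @property
    def depth(self) -> int:
        return len(self.proteins)

    @property
    def nodes(self) -> list[Node]:
        return [self.drug, *self.proteins, self.side_effect]

    @property
    def pairs(self) -> list[tuple[Node, Node]]:
        ns = self.nodes
        return list(zip(ns[:-1], ns[1:]))

    def key(self) -> tuple[str, ...]:
        """Deterministic identity: drug id, protein ids, side-effect id."""
        return (self.drug[0], *[p[0] for p in self.proteins],
                self.side_effect[0])


def build_graph(
    triples: Iterable[RelationTriple],
    drug_whitelist: set[str] | None = None,
    include_negated: bool = False,
) -> KnowledgeGraph:
    """Merge triples into a knowledge graph.

    Negated assertions are excluded by default; drug nodes outside
    *drug_whitelist* (canonical ids), when given, are dropped together
    with their edges.
    """
    kg = KnowledgeGraph()
    for t in triples:
        if t.negated and not include_negated:
            continue
        if drug_whitelist is not None:
            if (t.source.entity_type == DRUG
                    and t.source.canonical_id not in drug_whitelist):
                continue
        kg.add_triple(t)
    return kg


def enumerate_paths(kg: KnowledgeGraph, k: int) -> list[KnowledgePath]:
    """All simple drug →(k protein hops)→ side-effect paths in the graph,
    in lexicographic node-id order."""
    if not 1 <= k <= MAX_DEPTH:
        raise ValueError(f"k must be 1..{MAX_DEPTH}, got {k}")
    g = kg.g
    paths: list[KnowledgePath] = []

    def walk(prefix: list[Node]) -> None:
        here = prefix[-1]
        if len(prefix) == k + 1:  # drug + k proteins: close with an SE
            for nxt in sorted(g.successors(here)):
                if nxt[1] == SIDE_EFFECT:
                    paths.append(_make_path(kg, prefix + [nxt]))
            return
        for nxt in sorted(g.successors(here)):
            if nxt[1] == PROTEIN and nxt not in prefix:
                walk(prefix + [nxt])

    for drug in kg.nodes_of_type(DRUG):
        walk([drug])
    paths.sort(key=lambda p: p.key())
    return paths


def _make_path(kg: KnowledgeGraph, nodes: list[Node]) -> KnowledgePath:
    verbs = []
    pols = []
    for u, v in zip(nodes[:-1], nodes[1:]):
        data = kg.edge_data(u, v)
        verbs.append(frozenset(data["verbs"]))
        pols.append(frozenset(data["polarities"]))
    return KnowledgePath(drug=nodes[0], proteins=nodes[1:-1],
                         side_effect=nodes[-1], edge_verbs=verbs,
                         edge_polarities=pols)


def _default_significant(polarities: frozenset[str]) -> bool:
    return bool(polarities & {INCREASE, DECREASE})


def filter_significant(
    paths: Iterable[KnowledgePath],
    effect_terms: Iterable[str] = DEFAULT_EFFECT_TERMS,
    significant: Callable[[frozenset[str]], bool] = _default_significant,
    side_effect_names: dict[Node, str] | None = None,
) -> list[KnowledgePath]:
    """Drop intended-effect endpoints and non-directional paths.

    A path is removed when its side-effect name contains any effect
    term (case-insensitive substring), or when any edge except the
    terminal protein→side-effect edge fails the *significant* predicate
    (default: carries at least one increase/decrease verb).  The
    terminal edge may be merely associative.
    """
    terms = {t.lower() for t in effect_terms}
    kept: list[KnowledgePath] = []
    for p in paths:
        name = (side_effect_names or {}).get(p.side_effect, p.side_effect[0])
        low = name.lower()
        if any(t in low for t in terms):
            continue
        if p.edge_polarities and not all(
                significant(pol) for pol in p.edge_polarities[:-1]):
            continue
        kept.append(p)
    return kept


# --------------------------------------------------------------------------
# TSV exchange
# --------------------------------------------------------------------------

def write_edges_tsv(kg: KnowledgeGraph, stream: IO[str]) -> None:
    stream.write("source_id\tsource_type\tverbs\tpolarities\tsupport\t"
                 "target_id\ttarget_type\n")
    for u, v, d in sorted(kg.g.edges(data=True)):
        stream.write("\t".join([
            u[0], u[1], "|".join(sorted(d["verbs"])),
            "|".join(sorted(d["polarities"])), str(d["support"]),
            v[0], v[1]]) + "\n")


def read_edges_tsv(stream: IO[str] | Iterable[str]) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    it = iter(stream)
    next(it, None)
    for line in it:
        if not line.strip():
            continue
        sid, stype, verbs, pols, support, tid, ttype = (
            line.rstrip("\n").split("\t"))
        u, v = (sid, stype), (tid, ttype)
        for node in (u, v):
            if node not in kg.g:
                kg.g.add_node(node, name=node[0])
        kg.g.add_edge(u, v, verbs=set(verbs.split("|")),
                      polarities=set(pols.split("|")),
                      support=int(support), provenance=[])
    return kg


def write_paths_tsv(paths: Iterable[KnowledgePath], stream: IO[str],
                    names: dict[Node, str] | None = None) -> None:
    """Path table: drug, verb1, protein1, ..., verbN, side effect."""
    names = names or {}
    for p in paths:
        cells: list[str] = [names.get(p.drug, p.drug[0])]
        for verbs, node in zip(p.edge_verbs, p.nodes[1:]):
            cells.append(", ".join(sorted(verbs)))
            cells.append(names.get(node, node[0]))
        stream.write("\t".join(cells) + "\n")
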