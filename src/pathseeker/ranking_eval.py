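"""Path ranking and precision-at-k evaluation.

Each consecutive entity pair (vi, vj) on a candidate path is scored by
a weighted combination of three bounded components:

    pair_weight = α·COALS(vi, vj)
                + β·LocalFreq(vi, vj, SE) / MaxLocalFreq(SE)
                + γ·hierarchy(vi, vj)

where LocalFreq counts how often the pair occurs across all candidate
paths ending in the same side effect SE, and MaxLocalFreq is the
largest such count for that side effect.  The path score is the mean of
its pair weights and paths are ranked by descending score.  Defaults
α, β, γ = 0.3, 0.4, 0.3.

Three single-component baselines (co-occurrence support, COALS-only,
hierarchy-only) and precision-at-k against plausibility labels support
comparative evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Sequence

from .graph_paths import KnowledgeGraph, KnowledgePath, Node
from .semantic_similarity import (CoalsModel, ConceptHierarchy,
                                  coals_similarity, hierarchy_similarity)

__all__ = [
    "RankingWeights",
    "RankedPath",
    "LocalFrequencyTable",
    "local_frequency",
    "entity_pair_weight",
    "path_score",
    "rank_paths",
    "baseline_scores",
    "precision_at_k",
    "COOCCURRENCE",
    "COALS_ONLY",
    "HIERARCHY_ONLY",
]

COOCCURRENCE = "COOCCURRENCE"
COALS_ONLY = "COALS_ONLY"
HIERARCHY_ONLY = "HIERARCHY_ONLY"


@dataclass(frozen=True)
class RankingWeights:
    """Non-negative component weights summing to one (renormalized with
    a warning otherwise)."""

    alpha: float = 0.3
    beta: float = 0.4
    gamma: float = 0.3

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be non-negative")
        total = self.alpha + self.beta + self.gamma
        if total == 0:
            raise ValueError("weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(f"weights sum to {total:g}; renormalizing")
            object.__setattr__(self, "alpha", self.alpha / total)
            object.__setattr__(self, "beta", self.beta / total)
            object.__setattr__(self, "gamma", self.gamma / total)


@dataclass
class RankedPath:
    path: KnowledgePath
    pair_weights: list[float]
    score: float
    rank: int = 0


class LocalFrequencyTable:
    """Per-side-effect counts of consecutive entity pairs across a
    candidate path set."""

    def __init__(self, paths: Iterable[KnowledgePath] = ()) -> None:
        self._counts: dict[str, dict[tuple[str, str], int]] = {}
        for p in paths:
            self.add_path(p)

    def add_path(self, p: KnowledgePath) -> None:
        se = p.side_effect[0]
        table = self._counts.setdefault(se, {})
        for u, v in p.pairs:
            key = (u[0], v[0])
            table[key] = table.get(key, 0) + 1

    def frequency(self, vi: str, vj: str, side_effect_id: str) -> int:
        return self._counts.get(side_effect_id, {}).get((vi, vj), 0)

    def max_frequency(self, side_effect_id: str) -> int:
        table = self._counts.get(side_effect_id, {})
        return max(table.values(), default=0)


def local_frequency(table: LocalFrequencyTable, vi: str, vj: str,
                    side_effect_id: str) -> int:
    """Occurrences of edge (vi, vj) among all candidate paths that end
    in *side_effect_id*."""
    return table.frequency(vi, vj, side_effect_id)


def entity_pair_weight(
    vi: str,
    vj: str,
    se_id: str,
    coals: CoalsModel | None,
    hier: ConceptHierarchy | None,
    freq_table: LocalFrequencyTable,
    w: RankingWeights = RankingWeights(),
) -> float:
    """Weighted combination of the three pair components, in [0, 1].

    A side effect with MaxLocalFreq 0 contributes 0 for the frequency
    term; a missing COALS model or hierarchy contributes 0 for its
    term.
    """
    c = coals_similarity(coals, vi, vj) if coals is not None else 0.0
    maxf = freq_table.max_frequency(se_id)
    f = freq_table.frequency(vi, vj, se_id) / maxf if maxf > 0 else 0.0
    u = hierarchy_similarity(hier, vi, vj) if hier is not None else 0.0
    return w.alpha * c + w.beta * f + w.gamma * u


def path_score(p: KnowledgePath,
               pair_weight_fn: Callable[[str, str, str], float]
               ) -> tuple[float, list[float]]:
    """Mean of the consecutive pair weights along the path."""
    se = p.side_effect[0]
    weights = [pair_weight_fn(u[0], v[0], se) for u, v in p.pairs]
    return sum(weights) / len(weights), weights


def rank_paths(
    paths: Sequence[KnowledgePath],
    scorer: Callable[[KnowledgePath], tuple[float, list[float]]],
) -> list[RankedPath]:
    """Stable descending sort by score; ties broken lexicographically by
    (drug id, protein ids, side-effect id)."""
    scored = []
    for p in paths:
        score, weights = scorer(p)
        scored.append(RankedPath(path=p, pair_weights=weights, score=score))
    scored.sort(key=lambda rp: (-rp.score, rp.path.key()))
    for i, rp in enumerate(scored, 1):
        rp.rank = i
    return scored


def make_scorer(
    coals: CoalsModel | None,
    hier: ConceptHierarchy | None,
    freq_table: LocalFrequencyTable,
    w: RankingWeights = RankingWeights(),
) -> Callable[[KnowledgePath], tuple[float, list[float]]]:
    """Bind models and weights into a path scorer for rank_paths."""

    def scorer(p: KnowledgePath) -> tuple[float, list[float]]:
        return path_score(
            p, lambda vi, vj, se: entity_pair_weight(
                vi, vj, se, coals, hier, freq_table, w))

    return scorer


def baseline_scores(
    paths: Sequence[KnowledgePath],
    mode: str,
    kg: KnowledgeGraph | None = None,
    coals: CoalsModel | None = None,
    hier: ConceptHierarchy | None = None,
) -> list[float]:
    """Single-component reference rankers.

    COOCCURRENCE: mean over path edges of graph support normalized by
    the maximum edge support.  COALS_ONLY / HIERARCHY_ONLY: mean pair
    similarity from the respective model alone (identical to the
    combined scorer with degenerate weights).
    """
    if mode == COOCCURRENCE:
        if kg is None:
            raise ValueError("co-occurrence baseline needs the graph")
        max_support = max(
            (d["support"] for _, _, d in kg.g.edges(data=True)), default=0)

        def pair(u: Node, v: Node) -> float:
            if max_support == 0 or not kg.g.has_edge(u, v):
                return 0.0
            return kg.edge_data(u, v)["support"] / max_support

    elif mode == COALS_ONLY:
        if coals is None:
            raise ValueError("COALS baseline needs a trained model")

        def pair(u: Node, v: Node) -> float:
            return coals_similarity(coals, u[0], v[0])

    elif mode == HIERARCHY_ONLY:
        if hier is None:
            raise ValueError("hierarchy baseline needs a hierarchy")

        def pair(u: Node, v: Node) -> float:
            return hierarchy_similarity(hier, u[0], v[0])

    else:
        raise ValueError(f"unknown baseline mode {mode!r}")

    return [sum(pair(u, v) for u, v in p.pairs) / len(p.pairs)
            for p in paths]


def precision_at_k(ranked_labels: Sequence[str], k: int,
                   true_labels: Iterable[str]) -> float:
    """Fraction of the top-k ranked items whose label is in
    *true_labels*."""
    if not 1 <= k <= len(ranked_labels):
        raise ValueError(f"k must be in 1..{len(ranked_labels)}, got {k}")
    truth = set(true_labels)
    hits = sum(1 for lab in ranked_labels[:k] if lab in truth)
    return hits / k


def read_labels_tsv(stream: IO[str] | Iterable[str]) -> dict[str, str]:
    """Labels file: path_id<TAB>TYPE1|TYPE2|TYPE3."""
    labels: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        pid, label = line.split("\t")
        if label not in {"TYPE1", "TYPE2", "TYPE3"}:
            raise ValueError(f"unknown label {label!r}")
        if pid in labels:
            raise ValueError(f"duplicate label for path {pid!r}")
        labels[pid] = label
    return labels
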