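"""Corpus- and hierarchy-based semantic similarity.

Two complementary signals score how related a pair of entities is:

* **COALS** (Correlated Occurrence Analogue to Lexical Semantics): a
  word-space model built from ramped-window co-occurrence counts.  Each
  count is replaced by the pairwise correlation between its row and
  column events, negative correlations are zeroed, positive ones
  square-rooted, and similarity between two terms is the Pearson
  correlation of their resulting vectors (clamped at 0).

* **Concept-hierarchy similarity**: Wu–Palmer score
  ``2·depth(lcs) / (depth(a) + depth(b))`` over a rooted is-a taxonomy
  (root depth 1), with a rescaled shortest-path measure available as an
  alternative.

Multi-token entity names are collapsed to their canonical id before
counting, so entity–entity similarity is well-defined.
"""

from __future__ import annotations

import warnings
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "CoalsModel",
    "train_coals",
    "coals_similarity",
    "ConceptHierarchy",
    "load_hierarchy",
    "hierarchy_similarity",
]


# --------------------------------------------------------------------------
# COALS
# --------------------------------------------------------------------------

class CoalsModel:
    """Trained COALS word space: a vocabulary index and one non-negative
    vector per term over the ``dim`` highest-frequency column terms."""

    def __init__(self, vocabulary: Sequence[str], columns: Sequence[str],
                 vectors: np.ndarray, window: int) -> None:
        self.vocabulary = list(vocabulary)
        self.columns = list(columns)
        self.vectors = np.asarray(vectors, dtype=float)
        self.window = window
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        if self.vectors.shape != (len(self.vocabulary), len(self.columns)):
            raise ValueError("vector matrix shape mismatch")

    @property
    def dim(self) -> int:
        return len(self.columns)

    def vector(self, term: str) -> np.ndarray | None:
        i = self._index.get(term)
        return None if i is None else self.vectors[i]

    def save(self, path: str) -> None:
        np.savez(path, vectors=self.vectors,
                 vocabulary=np.array(self.vocabulary, dtype=object),
                 columns=np.array(self.columns, dtype=object),
                 window=np.array([self.window]))

    @classmethod
    def load(cls, path: str) -> "CoalsModel":
        d = np.load(path, allow_pickle=True)
        return cls(list(d["vocabulary"]), list(d["columns"]),
                   d["vectors"], int(d["window"][0]))


def _ramped_counts(sentences: Iterable[Sequence[str]], vocab: dict[str, int],
                   window: int) -> np.ndarray:
    """Co-occurrence counts where a neighbor at distance d contributes
    weight window + 1 - d (d = 1..window); windows do not cross sentence
    boundaries."""
    n = len(vocab)
    counts = np.zeros((n, n), dtype=float)
    for toks in sentences:
        idx = [vocab[t] for t in toks]
        for i, wi in enumerate(idx):
            for d in range(1, window + 1):
                j = i + d
                if j >= len(idx):
                    break
                w = window + 1 - d
                counts[wi, idx[j]] += w
                counts[idx[j], wi] += w
    return counts


def _correlation_normalize(counts: np.ndarray) -> np.ndarray:
    """Replace each count by the correlation of its row/column events:

    corr_ab = (T·w_ab − r_a·c_b) / sqrt(r_a (T−r_a) c_b (T−c_b))

    then zero negatives and square-root positives.
    """
    r = counts.sum(axis=1, keepdims=True)
    c = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    num = total * counts - r * c
    denom_sq = r * (total - r) * c * (total - c)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom_sq > 0, num / np.sqrt(denom_sq), 0.0)
    return np.sqrt(np.clip(corr, 0.0, None))


def train_coals(sentences: Iterable[Sequence[str]], window: int = 4,
                dim: int | None = None) -> CoalsModel:
    """Train a COALS model on tokenized sentences.

    *sentences* should already have entity mentions collapsed to their
    canonical ids.  *dim* caps the column space to that many
    highest-frequency terms (ties broken lexicographically); ``None``
    keeps every term.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sentences = [list(s) for s in sentences]
    if not any(sentences):
        raise ValueError("corpus is empty")
    freq: dict[str, int] = {}
    for toks in sentences:
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    vocabulary = sorted(freq)
    if dim is not None and dim < 1:
        raise ValueError("dim must be >= 1")
    n_cols = len(vocabulary) if dim is None else min(dim, len(vocabulary))
    columns = sorted(sorted(freq), key=lambda t: (-freq[t], t))[:n_cols]
    vocab_index = {w: i for i, w in enumerate(vocabulary)}
    counts = _ramped_counts(sentences, vocab_index, window)
    col_idx = [vocab_index[c] for c in columns]
    vectors = _correlation_normalize(counts[:, col_idx])
    return CoalsModel(vocabulary, columns, vectors, window)


def coals_similarity(m: CoalsModel, a: str, b: str) -> float:
    """Pearson correlation of the two term vectors, clamped to [0, 1].

    Unknown terms and all-zero vectors score 0.
    """
    va, vb = m.vector(a), m.vector(b)
    if va is None or vb is None:
        warnings.warn(f"term not in COALS vocabulary: "
                      f"{a if va is None else b!r}")
        return 0.0
    if not va.any() or not vb.any():
        return 0.0
    if np.array_equal(va, vb):
        return 1.0
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(va, vb)[0, 1])
    return float(min(1.0, max(0.0, r)))


# --------------------------------------------------------------------------
# Concept hierarchy
# --------------------------------------------------------------------------

ROOT = "ROOT"


class ConceptHierarchy:
    """Rooted is-a DAG over concept ids.

    Built from child→parent edges; the root has no parent.  ``depth`` is
    the length of the shortest root-to-node chain, with the root at
    depth 1.  Entity ids may be mapped onto concept ids via *mapping*
    (identity by default).
    """

    def __init__(self, parents: dict[str, set[str]], root: str = ROOT,
                 mapping: dict[str, str] | None = None) -> None:
        self.root = root
        self.parents = {c: set(ps) for c, ps in parents.items()}
        self.parents.setdefault(root, set())
        self.mapping = dict(mapping or {})
        self._depth: dict[str, int] = {}
        self._compute_depths()

    def _compute_depths(self) -> None:
        children: dict[str, set[str]] = {}
        for c, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(c)
        self._depth[self.root] = 1
        frontier = [self.root]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for ch in children.get(node, ()):
                    d = self._depth[node] + 1
                    if ch not in self._depth or d < self._depth[ch]:
                        self._depth[ch] = d
                        nxt.append(ch)
            frontier = nxt
        unreachable = set(self.parents) - set(self._depth)
        if unreachable:
            raise ValueError(
                f"nodes unreachable from root: {sorted(unreachable)[:5]}")

    def __contains__(self, concept: str) -> bool:
        return concept in self.parents

    def resolve(self, entity_id: str) -> str | None:
        concept = self.mapping.get(entity_id, entity_id)
        return concept if concept in self.parents else None

    def depth(self, concept: str) -> int:
        return self._depth[concept]

    @property
    def max_depth(self) -> int:
        return max(self._depth.values())

    def ancestors(self, concept: str) -> set[str]:
        """All ancestors including the concept itself."""
        seen = {concept}
        frontier = [concept]
        while frontier:
            node = frontier.pop()
            for p in self.parents.get(node, ()):
                if p not in seen:
                    seen.add(p)
                    frontier.append(p)
        return seen

    def lcs(self, a: str, b: str) -> str:
        """Deepest common ancestor (ties broken lexicographically)."""
        common = self.ancestors(a) & self.ancestors(b)
        return max(sorted(common), key=lambda c: self._depth[c])


def load_hierarchy(stream: IO[str] | Iterable[str],
                   mapping: dict[str, str] | None = None,
                   root: str = ROOT) -> ConceptHierarchy:
    """Read child<TAB>parent edges; the root row has parent ``-``."""
    parents: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected child<TAB>parent")
        child, parent = parts[0].strip(), parts[1].strip()
        if parent == "-":
            root = child
            parents.setdefault(child, set())
        else:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    return ConceptHierarchy(parents, root=root, mapping=mapping)


def hierarchy_similarity(h: ConceptHierarchy, a: str, b: str,
                         method: str = "wu-palmer") -> float:
    """Similarity of two entity ids through the concept hierarchy.

    ``wu-palmer`` (default): 2·depth(lcs) / (depth(a) + depth(b)).
    ``path``: 1 / (1 + shortest is-a path length between a and b via
    their LCS) — a bounded path-length alternative.
    Unmapped entities score 0; identical mapped entities score 1.
    """
    ca, cb = h.resolve(a), h.resolve(b)
    if ca is None or cb is None:
        return 0.0
    if ca == cb:
        return 1.0
    lcs = h.lcs(ca, cb)
    if method == "wu-palmer":
        return 2.0 * h.depth(lcs) / (h.depth(ca) + h.depth(cb))
    if method == "path":
        dist = (h.depth(ca) - h.depth(lcs)) + (h.depth(cb) - h.depth(lcs))
        return 1.0 / (1.0 + dist)
    raise ValueError(f"unknown method {method!r}")
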