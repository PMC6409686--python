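"""COALS word space and concept-hierarchy similarity, each checked
against a direct-formula oracle."""

import io
import math
import random

import numpy as np
import pytest

from pathseeker.semantic_similarity import (ConceptHierarchy,
                                            coals_similarity,
                                            hierarchy_similarity,
                                            load_hierarchy, train_coals)

TOY_CORPUS = [
    "the drug inhibits the kinase".split(),
    "the kinase activates the receptor".split(),
    "the drug blocks the receptor".split(),
    "a hormone stimulates secretion".split(),
    "the hormone regulates secretion".split(),
]


# --------------------------------------------------------------------------
# oracle: COALS correlation computed cell by cell from first principles
# --------------------------------------------------------------------------

def oracle_coals_matrix(sentences, window):
    vocab = sorted({t for s in sentences for t in s})
    idx = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)
    counts = [[0.0] * n for _ in range(n)]
    for toks in sentences:
        for i, a in enumerate(toks):
            for j, b in enumerate(toks):
                d = abs(i - j)
                if 1 <= d <= window:
                    counts[idx[a]][idx[b]] += window + 1 - d
    total = sum(map(sum, counts))
    rows = [sum(r) for r in counts]
    cols = [sum(counts[i][j] for i in range(n)) for j in range(n)]
    out = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            denom = rows[a] * (total - rows[a]) * cols[b] * (total - cols[b])
            if denom <= 0:
                corr = 0.0
            else:
                corr = (total * counts[a][b] - rows[a] * cols[b]) \
                    / math.sqrt(denom)
            out[a][b] = math.sqrt(corr) if corr > 0 else 0.0
    return vocab, out


class TestCoalsTraining:
    def test_matches_formula_oracle_on_toy_corpus(self):
        model = train_coals(TOY_CORPUS, window=4)
        vocab, expected = oracle_coals_matrix(TOY_CORPUS, window=4)
        assert model.vocabulary == vocab
        # model columns are frequency-ordered; realign to oracle order
        col = {c: j for j, c in enumerate(model.columns)}
        for a, wa in enumerate(vocab):
            for b, wb in enumerate(vocab):
                got = model.vectors[a, col[wb]]
                assert got == pytest.approx(expected[a][b], abs=1e-10)

    def test_identical_context_terms_get_identical_vectors(self):
        corpus = [["left", "aaa", "right"], ["left", "bbb", "right"]] * 3
        model = train_coals(corpus, window=2)
        va, vb = model.vector("aaa"), model.vector("bbb")
        assert np.allclose(va, vb)

    def test_vectors_nonnegative(self):
        model = train_coals(TOY_CORPUS, window=4)
        assert (model.vectors >= 0).all()

    def test_dim_truncation_keeps_most_frequent_columns(self):
        model = train_coals(TOY_CORPUS, window=4, dim=3)
        assert model.dim == 3
        assert "the" in model.columns  # most frequent token

    def test_bad_arguments(self):
        with pytest.raises(ValueError, match="dim"):
            train_coals(TOY_CORPUS, dim=0)
        with pytest.raises(ValueError, match="window"):
            train_coals(TOY_CORPUS, window=0)
        with pytest.raises(ValueError, match="empty"):
            train_coals([])


@pytest.fixture(scope="module")
def model():
    return train_coals(TOY_CORPUS, window=4)


class TestCoalsSimilarity:

    def test_self_similarity_is_one(self, model):
        for term in ("drug", "kinase", "hormone"):
            assert coals_similarity(model, term, term) == 1.0

    def test_symmetric_and_bounded(self, model):
        for a in model.vocabulary:
            for b in model.vocabulary:
                s = coals_similarity(model, a, b)
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(coals_similarity(model, b, a))

    def test_unknown_term_scores_zero_with_warning(self, model):
        with pytest.warns(UserWarning, match="vocabulary"):
            assert coals_similarity(model, "drug", "unseen") == 0.0

    def test_planted_cooccurrence_ordering(self):
        """Terms that always co-occur are closer than terms that never
        share a context."""
        rng = random.Random(0)
        corpus = []
        for _ in range(40):
            corpus.append(["A", "B", rng.choice(["x1", "x2", "x3"])])
            corpus.append(["C", rng.choice(["y1", "y2", "y3"]), "y4"])
        model = train_coals(corpus, window=4)
        assert coals_similarity(model, "A", "B") > \
            coals_similarity(model, "A", "C")


# --------------------------------------------------------------------------
# hierarchy similarity with exhaustive-LCS oracle
# --------------------------------------------------------------------------

def random_tree(seed, n=30):
    """Random rooted tree as child->parent lines."""
    rng = random.Random(seed)
    lines = ["ROOT\t-"]
    nodes = ["ROOT"]
    for i in range(1, n):
        parent = rng.choice(nodes)
        lines.append(f"N{i}\t{parent}")
        nodes.append(f"N{i}")
    return load_hierarchy(io.StringIO("\n".join(lines)))


def oracle_wu_palmer(h: ConceptHierarchy, a: str, b: str) -> float:
    """Independent: chase parent chains, intersect ancestor sets, take
    the deepest common ancestor by recomputed depth."""

    def chain_depth(node):
        d = 1
        while node != h.root:
            node = next(iter(h.parents[node]))
            d += 1
        return d

    def ancestors(node):
        out = {node}
        while node != h.root:
            node = next(iter(h.parents[node]))
            out.add(node)
        return out

    if a == b:
        return 1.0
    common = ancestors(a) & ancestors(b)
    lcs_depth = max(chain_depth(c) for c in common)
    return 2.0 * lcs_depth / (chain_depth(a) + chain_depth(b))


class TestHierarchySimilarity:
    def test_identity(self):
        h = random_tree(0)
        assert hierarchy_similarity(h, "N5", "N5") == 1.0

    def test_siblings_closed_form(self):
        h = load_hierarchy(io.StringIO(
            "ROOT\t-\nmid\tROOT\na\tmid\nb\tmid\n"))
        # siblings at depth 3 under a parent at depth 2
        assert hierarchy_similarity(h, "a", "b") == pytest.approx(
            2 * 2 / (3 + 3))

    def test_unmapped_entity_scores_zero(self):
        h = random_tree(1)
        assert hierarchy_similarity(h, "N3", "never-seen") == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lcs_oracle_on_random_trees(self, seed):
        h = random_tree(seed)
        nodes = sorted(h.parents)
        for a in nodes:
            for b in nodes:
                assert hierarchy_similarity(h, a, b) == pytest.approx(
                    oracle_wu_palmer(h, a, b))

    def test_symmetric_and_bounded(self):
        h = random_tree(3)
        nodes = sorted(h.parents)[:12]
        for a in nodes:
            for b in nodes:
                s = hierarchy_similarity(h, a, b)
                assert 0 <= s <= 1
                assert s == hierarchy_similarity(h, b, a)

    def test_shallower_lcs_scores_less(self):
        h = load_hierarchy(io.StringIO(
            "ROOT\t-\nm1\tROOT\nm2\tm1\na\tm2\nb\tm2\nc\tm1\nd\tROOT\n"))
        # same depths for a fixed pair: lcs m2 (depth 3) vs m1 (depth 2)
        assert hierarchy_similarity(h, "a", "b") > \
            hierarchy_similarity(h, "a", "c")

    def test_path_method_bounded(self):
        h = random_tree(4)
        s = hierarchy_similarity(h, "N2", "N7", method="path")
        assert 0 < s <= 1

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="unreachable"):
            load_hierarchy(io.StringIO("ROOT\t-\na\tb\nb\ta\n"))

    def test_entity_mapping(self):
        h = load_hierarchy(io.StringIO("ROOT\t-\nc1\tROOT\n"),
                           mapping={"drugX": "c1"})
        assert hierarchy_similarity(h, "drugX", "drugX") == 1.0
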