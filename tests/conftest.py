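"""Shared fixtures: synthetic corpora and small lexicons."""

from __future__ import annotations

import io

import pytest

from pathseeker import (generate_corpus, load_bioverbs, load_hierarchy,
                        load_lexicon, run_extraction)
from pathseeker.lexicon_ner import DRUG, PROTEIN, SIDE_EFFECT


def load_bundle_lexicons(corpus):
    return {
        DRUG: load_lexicon(io.StringIO(corpus.drug_lexicon_tsv), DRUG),
        PROTEIN: load_lexicon(io.StringIO(corpus.protein_lexicon_tsv),
                              PROTEIN),
        SIDE_EFFECT: load_lexicon(
            io.StringIO(corpus.side_effect_lexicon_tsv), SIDE_EFFECT),
    }


@pytest.fixture(scope="session")
def synthetic_bundle():
    """A 15-document corpus with 10 planted chains and distractors,
    mined end to end."""
    corpus = generate_corpus(n_docs=15, n_chains=10, seed=7)
    lexicons = load_bundle_lexicons(corpus)
    verbs = load_bioverbs(io.StringIO(corpus.verbs_tsv))
    hierarchy = load_hierarchy(io.StringIO(corpus.hierarchy_tsv))
    result = run_extraction(corpus.documents, lexicons, verbs)
    return {
        "corpus": corpus,
        "ground_truth": corpus.ground_truth,
        "lexicons": lexicons,
        "verbs": verbs,
        "hierarchy": hierarchy,
        "result": result,
    }


@pytest.fixture()
def toy_lexicons():
    """Tiny hand-written lexicons used across NER/relation tests."""
    drugs = "DB01\tsorafenib\tSORAFENIB\nDB02\ttamoxifen\n"
    proteins = ("UP01\tp38\tp38 mapk\n"
                "UP02\tgastrin\tg17|gastrin-17|little gastrin 1\n")
    ses = "SE01\tdyspepsia\tindigestion\nSE02\tbreast cancer\n"
    return {
        DRUG: load_lexicon(io.StringIO(drugs), DRUG),
        PROTEIN: load_lexicon(io.StringIO(proteins), PROTEIN),
        SIDE_EFFECT: load_lexicon(io.StringIO(ses), SIDE_EFFECT),
    }
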