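"""Relation-extraction rules and their brute-force oracle."""

import io

import pytest

from pathseeker import default_bioverbs
from pathseeker.corpus_io import RuleTagger, Sentence, tag_sentence
from pathseeker.lexicon_ner import (DRUG, PROTEIN, SIDE_EFFECT,
                                    EntityMention, match_entities)
from pathseeker.relation_extraction import (ACTIVE, PASSIVE, detect_negation,
                                            detect_voice, extract_relations,
                                            load_bioverbs)

VERBS = default_bioverbs()
TAGGER = RuleTagger(VERBS.lemmas)


def tagged(*tokens: str, pmid: str = "1", index: int = 0) -> Sentence:
    return tag_sentence(Sentence(pmid, index, list(tokens)), TAGGER)


def mention(cid, etype, start, end, s):
    return EntityMention(cid, etype, " ".join(s.tokens[start:end]),
                         s.doc_pmid, s.index, start, end)


# --------------------------------------------------------------------------
# brute-force oracle: re-checks every (pair, verb-position) combination
# directly against the five rules, independent of extract_relations
# --------------------------------------------------------------------------

_BE_AUX = {"be", "is", "are", "was", "were", "been", "being", "am",
           "do", "does", "did", "have", "has", "had", "will", "would",
           "can", "could", "may", "might", "shall", "should", "must"}
_CUES = {"not", "no", "never", "hardly", "scarcely", "n't", "neither",
         "nor", "without"}
_IRREG_PART = {"shown", "given", "found", "bound", "risen", "arisen",
               "undergone", "led", "become", "known", "seen", "taken",
               "made", "done"}
_ALLOWED = {(DRUG, PROTEIN), (PROTEIN, PROTEIN), (PROTEIN, SIDE_EFFECT)}


def oracle_extract(s, mentions, verbs, window=6):
    out = []
    ms = sorted(mentions, key=lambda m: (m.start, m.end))
    for a in range(len(ms)):
        for b in range(len(ms)):
            if a == b:
                continue
            m1, m2 = ms[a], ms[b]
            if m1.start > m2.start or m2.start < m1.end:
                continue
            if m2.start - m1.end > window:
                continue
            for v in range(m1.end, m2.start):
                if s.pos_tags[v] != "VERB":
                    continue
                lemma = s.lemmas[v]
                pol = verbs.polarity(lemma)
                if pol is None:
                    continue
                low = s.tokens[v].lower()
                participle = (low in _IRREG_PART
                              or (low.endswith("ed") and low != lemma)
                              or (lemma.endswith("e") and low == lemma + "d"))
                passive = participle and any(
                    t.lower() in _BE_AUX
                    for t in s.tokens[max(0, v - 2):v])
                src, tgt = (m2, m1) if passive else (m1, m2)
                if (src.entity_type, tgt.entity_type) not in _ALLOWED:
                    continue
                neg = any(t.lower() in _CUES or t.lower().endswith("n't")
                          for t in s.tokens[max(0, v - 3):v])
                out.append((src.canonical_id, lemma, tgt.canonical_id,
                            pol, neg, PASSIVE if passive else ACTIVE))
    return sorted(out)


def as_tuples(triples):
    return sorted((t.source.canonical_id, t.verb_lemma,
                   t.target.canonical_id, t.polarity, t.negated, t.voice)
                  for t in triples)


class TestVerbLexicon:
    def test_polarity_lookup(self):
        assert VERBS.polarity("inhibit") == "DECREASE"
        assert VERBS.polarity("activate") == "INCREASE"
        assert VERBS.polarity("associate") == "NEUTRAL"
        assert VERBS.polarity("unknownverb") is None

    def test_unknown_polarity_label_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            load_bioverbs(io.StringIO("inhibit\tDOWNWARD\n"))

    def test_empty_lexicon_yields_no_triples(self, toy_lexicons):
        empty = load_bioverbs(io.StringIO(""))
        s = tagged("sorafenib", "inhibits", "p38")
        ms = match_entities(s, toy_lexicons)
        assert extract_relations(s, ms, empty) == []


class TestNegationAndVoice:
    @pytest.mark.parametrize("tokens,vidx,expected", [
        (("X", "does", "not", "inhibit", "Y"), 3, True),
        (("X", "hardly", "activates", "Y"), 2, True),
        (("X", "inhibits", "Y"), 1, False),
        (("X", "scarcely", "ever", "blocks", "Y"), 3, True),
        (("never", "seen", "before", "X", "inhibits", "Y"), 4, False),
    ])
    def test_negation_cue_window(self, tokens, vidx, expected):
        assert detect_negation(tagged(*tokens), vidx) is expected

    @pytest.mark.parametrize("tokens,vidx,expected", [
        (("A", "is", "activated", "by", "B"), 2, PASSIVE),
        (("B", "activates", "A"), 1, ACTIVE),
        (("A", "was", "inhibited", "by", "B"), 2, PASSIVE),
        (("A", "inhibited", "B"), 1, ACTIVE),  # simple past, no be-verb
        (("A", "was", "strongly", "suppressed", "by", "B"), 3, PASSIVE),
    ])
    def test_voice_patterns(self, tokens, vidx, expected):
        assert detect_voice(tagged(*tokens), vidx) == expected


class TestExtractRelations:
    def test_basic_active_triple(self, toy_lexicons):
        s = tagged("sorafenib", "inhibits", "p38")
        ms = match_entities(s, toy_lexicons)
        (t,) = extract_relations(s, ms, VERBS)
        assert (t.source.canonical_id, t.verb_lemma,
                t.target.canonical_id) == ("DB01", "inhibit", "UP01")
        assert t.voice == ACTIVE and not t.negated

    def test_passive_reverses_direction(self, toy_lexicons):
        s = tagged("p38", "is", "inhibited", "by", "sorafenib")
        ms = match_entities(s, toy_lexicons)
        (t,) = extract_relations(s, ms, VERBS)
        assert (t.source.canonical_id, t.target.canonical_id) == (
            "DB01", "UP01")
        assert t.voice == PASSIVE

    def test_active_and_passive_paraphrase_agree(self, toy_lexicons):
        active = tagged("sorafenib", "inhibits", "p38")
        passive = tagged("p38", "is", "inhibited", "by", "sorafenib")
        ta = extract_relations(active, match_entities(active, toy_lexicons),
                               VERBS)
        tp = extract_relations(passive,
                               match_entities(passive, toy_lexicons), VERBS)
        assert as_tuples(ta)[0][:3] == as_tuples(tp)[0][:3]

    def test_window_excludes_distant_pair(self, toy_lexicons):
        filler = ["in", "a", "broad", "series", "of", "many"]
        s = tagged("sorafenib", *filler, "inhibits", "p38")
        ms = match_entities(s, toy_lexicons)
        assert extract_relations(s, ms, VERBS, window=6) == []

    def test_gap_of_exactly_window_is_kept(self, toy_lexicons):
        filler = ["in", "a", "broad", "series", "of"]
        s = tagged("sorafenib", *filler, "inhibits", "p38")
        ms = match_entities(s, toy_lexicons)
        assert len(extract_relations(s, ms, VERBS, window=6)) == 1

    def test_multiple_verbs_yield_multiple_triples(self, toy_lexicons):
        s = tagged("sorafenib", "inhibits", "and", "blocks", "p38")
        ms = match_entities(s, toy_lexicons)
        lemmas = {t.verb_lemma for t in extract_relations(s, ms, VERBS)}
        assert lemmas == {"inhibit", "block"}

    def test_drug_never_a_target(self, synthetic_bundle):
        for t in synthetic_bundle["result"].triples:
            assert t.target.entity_type != DRUG
            assert t.verb_lemma in synthetic_bundle["verbs"]

    def test_shrinking_window_never_adds_triples(self, synthetic_bundle):
        res = synthetic_bundle["result"]
        lexicons = synthetic_bundle["lexicons"]
        verbs = synthetic_bundle["verbs"]
        for doc in res.documents[:6]:
            for s in doc.sentences:
                ms = match_entities(s, lexicons)
                sets = [as_tuples(extract_relations(s, ms, verbs, window=w))
                        for w in (1, 3, 6, 12)]
                for smaller, larger in zip(sets, sets[1:]):
                    assert set(smaller) <= set(larger)

    def test_matches_bruteforce_oracle_on_synthetic_sentences(
            self, synthetic_bundle):
        """Exhaustive rule check over 100+ tagged synthetic sentences."""
        res = synthetic_bundle["result"]
        lexicons = synthetic_bundle["lexicons"]
        verbs = synthetic_bundle["verbs"]
        n = 0
        for doc in res.documents:
            for s in doc.sentences:
                ms = match_entities(s, lexicons)
                got = as_tuples(extract_relations(s, ms, verbs))
                assert got == oracle_extract(s, ms, verbs)
                n += 1
        assert n >= 40  # every synthetic sentence checked

    def test_untagged_sentence_rejected(self, toy_lexicons):
        s = Sentence("1", 0, ["sorafenib", "inhibits", "p38"])
        ms = match_entities(s, toy_lexicons)
        with pytest.raises(ValueError, match="tagged"):
            extract_relations(s, ms, VERBS)
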