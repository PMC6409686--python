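"""Rule-based relation extraction.

A directed relation triple is asserted when two entity mentions in one
sentence are connected by a biomedical verb, subject to five rules:

1. basic entity–verb–entity structure (the verb lies strictly between
   the two mention spans);
2. the verb must belong to the biomedical verb lexicon, which also
   classifies it as INCREASE, DECREASE or NEUTRAL;
3. negation: a negation cue near the verb flags the triple as negated;
4. distance: at most ``window`` (default 6) tokens may separate the two
   mention spans;
5. direction: active voice points first→second mention, passive voice
   reverses the direction ("A is activated by B" means B activates A).

Only (DRUG→PROTEIN), (PROTEIN→PROTEIN) and (PROTEIN→SIDE_EFFECT)
assertions are kept.  Rules fire on POS/token patterns alone, so the
extractor runs offline without a dependency parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

from .corpus_io import Sentence, _BE_FORMS, _AUX_FORMS
from .lexicon_ner import DRUG, PROTEIN, SIDE_EFFECT, EntityMention

__all__ = [
    "INCREASE",
    "DECREASE",
    "NEUTRAL",
    "ACTIVE",
    "PASSIVE",
    "BioVerbLexicon",
    "RelationTriple",
    "load_bioverbs",
    "detect_negation",
    "detect_voice",
    "extract_relations",
    "write_triples_tsv",
    "read_triples_tsv",
    "ALLOWED_TYPE_PAIRS",
]

INCREASE = "INCREASE"
DECREASE = "DECREASE"
NEUTRAL = "NEUTRAL"
_POLARITIES = (INCREASE, DECREASE, NEUTRAL)

ACTIVE = "ACTIVE"
PASSIVE = "PASSIVE"

ALLOWED_TYPE_PAIRS = frozenset(
    {(DRUG, PROTEIN), (PROTEIN, PROTEIN), (PROTEIN, SIDE_EFFECT)})

NEGATION_CUES = frozenset(
    {"not", "no", "never", "hardly", "scarcely", "n't", "neither",
     "nor", "without"})

#: tokens before the verb inspected for a negation cue
NEGATION_WINDOW = 3
#: tokens before a participle inspected for a be/auxiliary form
PASSIVE_WINDOW = 2

DEFAULT_WINDOW = 6


class BioVerbLexicon:
    """Lookup from verb lemma to polarity class."""

    def __init__(self, polarities: dict[str, str] | None = None) -> None:
        self._pol: dict[str, str] = {}
        for lemma, pol in (polarities or {}).items():
            self.add(lemma, pol)

    def add(self, lemma: str, polarity: str) -> None:
        polarity = polarity.upper()
        if polarity not in _POLARITIES:
            raise ValueError(f"unknown polarity label {polarity!r}")
        self._pol[lemma.lower()] = polarity

    def polarity(self, lemma: str) -> str | None:
        return self._pol.get(lemma.lower())

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self._pol

    def __len__(self) -> int:
        return len(self._pol)

    @property
    def lemmas(self) -> set[str]:
        return set(self._pol)


def load_bioverbs(stream: IO[str] | Iterable[str]) -> BioVerbLexicon:
    """Read a ``lemma<TAB>polarity`` TSV into a verb lexicon."""
    lex = BioVerbLexicon()
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected lemma<TAB>polarity")
        lex.add(parts[0].strip(), parts[1].strip())
    return lex


@dataclass(frozen=True)
class RelationTriple:
    """Directed source→verb→target assertion with provenance."""

    source: EntityMention
    target: EntityMention
    verb_lemma: str
    polarity: str
    negated: bool
    voice: str
    pmid: str
    sentence_index: int

    def __post_init__(self) -> None:
        pair = (self.source.entity_type, self.target.entity_type)
        if pair not in ALLOWED_TYPE_PAIRS:
            raise ValueError(f"disallowed relation type pair {pair}")


def detect_negation(s: Sentence, verb_index: int) -> bool:
    """True when a negation cue occurs within NEGATION_WINDOW tokens
    before the verb (same sentence)."""
    lo = max(0, verb_index - NEGATION_WINDOW)
    for tok in s.tokens[lo:verb_index]:
        low = tok.lower()
        if low in NEGATION_CUES or low.endswith("n't"):
            return True
    return False


_PARTICIPLE_IRREGULAR = frozenset(
    {"shown", "given", "found", "bound", "risen", "arisen", "undergone",
     "led", "become", "known", "seen", "taken", "made", "done"})


def _is_past_participle(token: str, lemma: str) -> bool:
    low = token.lower()
    if low in _PARTICIPLE_IRREGULAR:
        return True
    # regular participle: surface derived from lemma with -ed/-d/-ied
    return (low.endswith("ed") and low != lemma) or (
        lemma.endswith("e") and low == lemma + "d")


def detect_voice(s: Sentence, verb_index: int) -> str:
    """PASSIVE when a be/auxiliary form occurs within PASSIVE_WINDOW
    tokens before a past-participle verb form, else ACTIVE."""
    tok = s.tokens[verb_index]
    lemma = (s.lemmas[verb_index] if s.lemmas else tok).lower()
    if not _is_past_participle(tok, lemma):
        return ACTIVE
    lo = max(0, verb_index - PASSIVE_WINDOW)
    for prev in s.tokens[lo:verb_index]:
        low = prev.lower()
        if low in _BE_FORMS or low in _AUX_FORMS:
            return PASSIVE
    return ACTIVE


def extract_relations(
    s: Sentence,
    mentions: Sequence[EntityMention],
    verbs: BioVerbLexicon,
    window: int = DEFAULT_WINDOW,
) -> list[RelationTriple]:
    """Apply all five rules to one tagged sentence.

    For every ordered pair of non-overlapping mentions (first before
    second in token order) whose inter-span gap is at most *window*
    tokens, each biomedical verb token strictly between them yields one
    triple; its direction follows the voice of that verb token.  Triples
    whose directed type pair is not drug→protein, protein→protein or
    protein→side-effect are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not s.lemmas or not s.pos_tags:
        raise ValueError("sentence must be tagged before extraction")
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    triples: list[RelationTriple] = []
    for i, m1 in enumerate(ordered):
        for m2 in ordered[i + 1:]:
            if m2.start < m1.end:
                continue  # overlapping spans never relate
            gap = m2.start - m1.end
            if gap > window:
                continue
            for v in range(m1.end, m2.start):
                if s.pos_tags[v] != "VERB":
                    continue
                lemma = s.lemmas[v]
                pol = verbs.polarity(lemma)
                if pol is None:
                    continue
                voice = detect_voice(s, v)
                src, tgt = (m1, m2) if voice == ACTIVE else (m2, m1)
                if (src.entity_type, tgt.entity_type) not in ALLOWED_TYPE_PAIRS:
                    continue
                triples.append(RelationTriple(
                    source=src, target=tgt, verb_lemma=lemma, polarity=pol,
                    negated=detect_negation(s, v), voice=voice,
                    pmid=s.doc_pmid, sentence_index=s.index))
    return triples


_TRIPLE_COLUMNS = ("pmid", "sentence_index", "source_id", "source_type",
                   "verb", "polarity", "negated", "voice", "target_id",
                   "target_type")


def write_triples_tsv(triples: Iterable[RelationTriple],
                      stream: IO[str]) -> None:
    stream.write("\t".join(_TRIPLE_COLUMNS) + "\n")
    for t in triples:
        stream.write("\t".join([
            t.pmid, str(t.sentence_index),
            t.source.canonical_id, t.source.entity_type,
            t.verb_lemma, t.polarity, str(int(t.negated)), t.voice,
            t.target.canonical_id, t.target.entity_type,
        ]) + "\n")


def read_triples_tsv(stream: IO[str] | Iterable[str]
                     ) -> Iterator[RelationTriple]:
    """Read triples back; mention spans are not stored in the TSV, so
    surfaces fall back to canonical ids and spans to [0, 1)."""
    it = iter(stream)
    header = next(it, None)
    if header is None:
        return
    for line in it:
        if not line.strip():
            continue
        (pmid, sidx, sid, stype, verb, pol, neg, voice, tid,
         ttype) = line.rstrip("\n").split("\t")
        src = EntityMention(sid, stype, sid, pmid, int(sidx), 0, 1)
        tgt = EntityMention(tid, ttype, tid, pmid, int(sidx), 0, 1)
        yield RelationTriple(src, tgt, verb, pol, bool(int(neg)), voice,
                             pmid, int(sidx))
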