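"""Dictionary-based named entity recognition.

Entity lexicons (drugs, proteins, side effects) are TSV files of
``canonical_id<TAB>canonical_name<TAB>synonym|synonym|...``.  Mentions
are recognized by exact matching of 1/2/3-gram token windows against the
synonym index, longest match first, left to right.  Matching is
case-insensitive by default while surfaces keep their original case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from .corpus_io import Sentence

__all__ = [
    "DRUG",
    "PROTEIN",
    "SIDE_EFFECT",
    "ENTITY_TYPES",
    "LexiconEntry",
    "Lexicon",
    "EntityMention",
    "load_lexicon",
    "save_lexicon",
    "match_entities",
    "mention_to_dict",
    "mention_from_dict",
]

DRUG = "DRUG"
PROTEIN = "PROTEIN"
SIDE_EFFECT = "SIDE_EFFECT"
ENTITY_TYPES = (DRUG, PROTEIN, SIDE_EFFECT)

MAX_NGRAM = 3

# When the same span matches in several lexicons, this priority decides
# which single mention survives (configurable in match_entities).
DEFAULT_TYPE_PRIORITY = (PROTEIN, DRUG, SIDE_EFFECT)


@dataclass
class LexiconEntry:
    canonical_id: str
    canonical_name: str
    entity_type: str
    synonyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        self.synonyms = set(self.synonyms) | {self.canonical_name}


@dataclass(frozen=True)
class EntityMention:
    """A matched span: half-open token interval [start, end) of length
    1..3 whose joined tokens equal the surface."""

    canonical_id: str
    entity_type: str
    surface: str
    pmid: str
    sentence_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.end - self.start <= MAX_NGRAM:
            raise ValueError("mention span must cover 1..3 tokens")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class Lexicon:
    """Entries of one entity type plus an inverted synonym index.

    The index maps a case-folded, whitespace-normalized synonym key to a
    single canonical id (first-wins on collision within the type).
    """

    def __init__(self, entity_type: str,
                 entries: Iterable[LexiconEntry] = (),
                 case_fold: bool = True) -> None:
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r}")
        self.entity_type = entity_type
        self.case_fold = case_fold
        self.entries: dict[str, LexiconEntry] = {}
        self._index: dict[str, str] = {}
        for e in entries:
            self.add(e)

    def _key(self, name: str) -> str:
        key = " ".join(name.split())
        return key.lower() if self.case_fold else key

    def add(self, entry: LexiconEntry) -> None:
        if entry.entity_type != self.entity_type:
            raise ValueError("entry type does not match lexicon type")
        if entry.canonical_id in self.entries:
            raise ValueError(f"duplicate canonical_id {entry.canonical_id!r}")
        self.entries[entry.canonical_id] = entry
        for syn in sorted(entry.synonyms):
            if not syn.strip():
                warnings.warn(
                    f"empty synonym for {entry.canonical_id!r} skipped")
                continue
            key = self._key(syn)
            if key in self._index and self._index[key] != entry.canonical_id:
                warnings.warn(
                    f"synonym {syn!r} already maps to "
                    f"{self._index[key]!r}; mapping for "
                    f"{entry.canonical_id!r} dropped")
                continue
            self._index[key] = entry.canonical_id

    def lookup(self, surface: str) -> str | None:
        return self._index.get(self._key(surface))

    @property
    def max_ngram(self) -> int:
        return min(MAX_NGRAM,
                   max((len(k.split()) for k in self._index), default=1))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())


def load_lexicon(stream: IO[str] | Iterable[str], entity_type: str,
                 case_fold: bool = True) -> Lexicon:
    """Read a lexicon TSV: canonical_id, canonical_name, pipe-separated
    synonyms (third column optional)."""
    lex = Lexicon(entity_type, case_fold=case_fold)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: need at least canonical_id "
                             "and canonical_name")
        cid, cname = parts[0].strip(), parts[1].strip()
        syns = set()
        if len(parts) > 2 and parts[2].strip():
            syns = {s.strip() for s in parts[2].split("|")}
        lex.add(LexiconEntry(cid, cname, entity_type, syns))
    return lex


def save_lexicon(lex: Lexicon, stream: IO[str]) -> None:
    for entry in sorted(lex, key=lambda e: e.canonical_id):
        syns = "|".join(sorted(entry.synonyms))
        stream.write(f"{entry.canonical_id}\t{entry.canonical_name}\t{syns}\n")


def match_entities(
    s: Sentence,
    lexicons: Mapping[str, Lexicon],
    type_priority: tuple[str, ...] = DEFAULT_TYPE_PRIORITY,
) -> list[EntityMention]:
    """Recognize entity mentions in a tokenized sentence.

    Every 1/2/3-gram of tokens is looked up in each lexicon; overlaps
    are resolved longest-match-first, ties by leftmost start, and
    same-span cross-type collisions by *type_priority*.  Returned
    mentions never overlap and are sorted by start position.
    """
    tokens = s.tokens
    n = len(tokens)
    prio = {t: i for i, t in enumerate(type_priority)}
    # candidates: (span length desc, start asc, type priority asc)
    candidates: list[tuple[int, int, int, EntityMention]] = []
    for start in range(n):
        for length in range(MAX_NGRAM, 0, -1):
            end = start + length
            if end > n:
                continue
            surface = " ".join(tokens[start:end])
            for etype, lex in lexicons.items():
                cid = lex.lookup(surface)
                if cid is None:
                    continue
                m = EntityMention(
                    canonical_id=cid, entity_type=lex.entity_type,
                    surface=surface, pmid=s.doc_pmid,
                    sentence_index=s.index, start=start, end=end)
                candidates.append(
                    (-length, start, prio.get(lex.entity_type, 99), m))
    candidates.sort(key=lambda c: c[:3])
    taken = [False] * n
    result: list[EntityMention] = []
    for _, _, _, m in candidates:
        if any(taken[i] for i in range(m.start, m.end)):
            continue
        for i in range(m.start, m.end):
            taken[i] = True
        result.append(m)
    result.sort(key=lambda m: (m.start, m.end))
    return result


def mention_to_dict(m: EntityMention) -> dict:
    return {
        "canonical_id": m.canonical_id,
        "entity_type": m.entity_type,
        "surface": m.surface,
        "pmid": m.pmid,
        "sentence_index": m.sentence_index,
        "start": m.start,
        "end": m.end,
    }


def mention_from_dict(d: dict) -> EntityMention:
    return EntityMention(**d)
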