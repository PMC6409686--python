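"""Bundled reference data.

* ``bioverbs.tsv`` — the default biomedical verb lexicon with
  increase/decrease/neutral polarity classes, used by the rule tagger
  and the relation extractor when no custom list is supplied.
* ``top20_paths.tsv`` / ``top20_labels.tsv`` — an expert-annotated
  reference ranking of 20 drug→protein→protein→protein→side-effect
  candidate paths mined from cancer-related abstracts, with per-path
  plausibility labels (TYPE1: entities and verbs both supported by the
  literature; TYPE2: entities supported, verbs uncertain; TYPE3: both
  uncertain).  It serves as the ground truth for precision-at-k
  evaluation of ranking functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .relation_extraction import BioVerbLexicon, load_bioverbs

__all__ = [
    "default_bioverbs",
    "ReferencePath",
    "load_reference_ranking",
]


def _read(name: str) -> list[str]:
    text = (resources.files("pathseeker.data") / name).read_text("utf-8")
    return text.splitlines()


def default_bioverbs() -> BioVerbLexicon:
    """The bundled verb lexicon."""
    return load_bioverbs(_read("bioverbs.tsv"))


@dataclass(frozen=True)
class ReferencePath:
    """One row of the bundled reference ranking."""

    rank: int
    drug: str
    proteins: tuple[str, ...]
    verbs: tuple[tuple[str, ...], ...]
    side_effect: str
    label: str


def load_reference_ranking() -> list[ReferencePath]:
    """The 20 labelled reference paths, in ranked order."""
    labels: dict[int, str] = {}
    for line in _read("top20_labels.tsv"):
        if line.strip():
            rank, label = line.split("\t")
            labels[int(rank)] = label
    paths: list[ReferencePath] = []
    rows = [ln for ln in _read("top20_paths.tsv") if ln.strip()]
    for line in rows[1:]:  # skip header
        cells = line.split("\t")
        rank = int(cells[0])
        drug = cells[1]
        side_effect = cells[-1]
        middle = cells[2:-1]
        verbs = tuple(tuple(v.strip() for v in middle[i].split(","))
                      for i in range(0, len(middle), 2))
        proteins = tuple(middle[i] for i in range(1, len(middle), 2))
        paths.append(ReferencePath(rank=rank, drug=drug, proteins=proteins,
                                   verbs=verbs, side_effect=side_effect,
                                   label=labels[rank]))
    paths.sort(key=lambda p: p.rank)
    return paths
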