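"""Deterministic synthetic corpora with planted ground truth.

The generator fabricates a small literature: drug→protein(→protein…)→
side-effect chains are planted as template sentences ("Zakulib inhibits
vik-21 .", "vik-21 is blocked by zakulib .") spread over MEDLINE-style
abstracts, together with the entity lexicons, verb list and a concept
hierarchy that the mining pipeline needs.  Every planted chain is
recoverable by construction, and distractor sentences violate exactly
one extraction rule each (negation cue, over-long gap, unknown verb),
so precision and recall of the full pipeline against the returned
:class:`GroundTruth` are both 1.0.

Entity names deliberately include hyphenated single tokens ("vik-21")
and multi-token names/synonyms ("acute zaosis", "little qek 1") to
exercise 1/2/3-gram dictionary matching.  Two whole-chain distractor
variants are also planted: a chain ending in a treated-condition name
(containing "tumor") and a chain whose first edge carries only a
neutral verb; both are enumerated as graph paths but removed by the
significance filter, and are therefore excluded from the ground-truth
path set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus_io import Document, documents_to_xml
from .lexicon_ner import DRUG, PROTEIN, SIDE_EFFECT
from .datasets import _read as _read_packaged

__all__ = ["GroundTruth", "PlantedChain", "SyntheticCorpus",
           "generate_corpus"]

_SYLLABLES = ["za", "qe", "xo", "vi", "ru", "mo", "ty", "ka", "lu", "pi",
              "ne", "so", "da", "fe", "gi", "ho", "ju", "ki", "lo", "mu"]

# directional verbs used on planted edges (all in the bundled lexicon)
_INCREASE_VERBS = ["activate", "stimulate", "induce", "enhance", "elevate"]
_DECREASE_VERBS = ["inhibit", "block", "reduce", "suppress", "silence"]
_NEUTRAL_VERBS = ["associate", "correlate", "interact"]

_FILLER = ["in", "a", "broad", "series", "of", "clinical", "observations"]

_LABELS = ("TYPE1", "TYPE2", "TYPE3")


def _code(n: int) -> str:
    """Pronounceable unique stem for integer n."""
    if n == 0:
        return _SYLLABLES[0]
    parts = []
    while n:
        parts.append(_SYLLABLES[n % len(_SYLLABLES)])
        n //= len(_SYLLABLES)
    return "".join(reversed(parts))


@dataclass(frozen=True)
class PlantedChain:
    """One planted drug→proteins→side-effect chain."""

    chain_id: int
    drug_id: str
    protein_ids: tuple[str, ...]
    side_effect_id: str
    edge_verbs: tuple[str, ...]
    depth: int
    label: str
    recoverable: bool  # False for whole-chain distractors


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact verification.

    Sentence indices count the title as sentence 0 of each document
    (matching segmentation with titles included).
    """

    seed: int
    mentions: list[tuple[str, int, int, int, str, str]] = field(
        default_factory=list)  # (pmid, sent_idx, start, end, id, type)
    triples: list[tuple[str, str, str, bool]] = field(
        default_factory=list)  # (source_id, verb, target_id, negated)
    chains: list[PlantedChain] = field(default_factory=list)
    sentence_counts: dict[str, int] = field(default_factory=dict)

    @property
    def recoverable_paths(self) -> list[PlantedChain]:
        return [c for c in self.chains if c.recoverable]

    @property
    def expected_triples(self) -> set[tuple[str, str, str]]:
        """Non-negated planted (source, verb, target) assertions."""
        return {(s, v, t) for s, v, t, neg in self.triples if not neg}


@dataclass
class SyntheticCorpus:
    """In-memory result of :func:`generate_corpus`."""

    documents: list[Document]
    drug_lexicon_tsv: str
    protein_lexicon_tsv: str
    side_effect_lexicon_tsv: str
    verbs_tsv: str
    hierarchy_tsv: str
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts (MEDLINE XML + TSVs) into *outdir*."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "corpus.xml": documents_to_xml(self.documents),
            "drugs.tsv": self.drug_lexicon_tsv,
            "proteins.tsv": self.protein_lexicon_tsv,
            "side_effects.tsv": self.side_effect_lexicon_tsv,
            "verbs.tsv": self.verbs_tsv,
            "hierarchy.tsv": self.hierarchy_tsv,
        }
        written = {}
        for name, content in files.items():
            p = out / name
            if isinstance(content, bytes):
                p.write_bytes(content)
            else:
                p.write_text(content, encoding="utf-8")
            written[name] = p
        return written


class _Namer:
    """Deterministic entity name/synonym factory."""

    def __init__(self, rng: random.Random) -> None:
        self.rng = rng

    def drug(self, c: int) -> tuple[str, list[str]]:
        name = _code(c) + "lib"
        return name, [name.upper()]

    def protein(self, c: int, j: int) -> tuple[str, list[str]]:
        stem = _code(c * 7 + j + 1)
        if j % 2 == 0:
            name = f"{stem}k-{c}{j}"  # hyphenated single token
            syns = [f"{stem}k{c}{j}"]
        else:
            name = f"{stem}in-17"
            syns = [f"little {stem} 1", f"{stem}in"]  # 3-gram synonym
        return name, syns

    def side_effect(self, c: int, effect_term: str | None = None
                    ) -> tuple[str, list[str]]:
        stem = _code(c * 13 + 3)
        if effect_term:
            name = f"{stem} {effect_term}"  # intended-effect endpoint
            return name, []
        name = f"acute {stem}osis"
        return name, [f"{stem}osis"]


def _lexicon_tsv(rows: list[tuple[str, str, list[str]]]) -> str:
    lines = []
    for cid, name, syns in rows:
        lines.append(f"{cid}\t{name}\t{'|'.join(syns)}" if syns
                     else f"{cid}\t{name}")
    return "\n".join(lines) + "\n"


def generate_corpus(
    n_docs: int,
    n_chains: int,
    depth_mix: Sequence[float] = (0.4, 0.3, 0.3),
    seed: int = 0,
    with_distractors: bool = True,
) -> SyntheticCorpus:
    """Generate a synthetic corpus with *n_chains* planted chains spread
    over *n_docs* abstracts.

    *depth_mix* gives the relative probability of chain depths 1, 2, 3.
    Regeneration with the same arguments is byte-identical.
    """
    if n_docs < 1 or n_chains < 1:
        raise ValueError("n_docs and n_chains must be >= 1")
    rng = random.Random(seed)
    namer = _Namer(rng)
    gt = GroundTruth(seed=seed)

    drugs: list[tuple[str, str, list[str]]] = []
    proteins: list[tuple[str, str, list[str]]] = []
    side_effects: list[tuple[str, str, list[str]]] = []
    name_of: dict[str, str] = {}
    syns_of: dict[str, list[str]] = {}

    def register(kind: list, cid: str, name: str, syns: list[str]) -> None:
        kind.append((cid, name, syns))
        name_of[cid] = name
        syns_of[cid] = syns

    depths = rng.choices((1, 2, 3), weights=depth_mix, k=n_chains)

    # ---- plant the regular chains -------------------------------------
    chains: list[PlantedChain] = []
    sentences: list[tuple[list[str],
                          list[tuple[int, int, str, str]],
                          list[tuple[str, str, str, bool]]]] = []
    # each: (tokens, mentions[(start,end,id,type)], triples)

    def surface_tokens(cid: str) -> list[str]:
        """Canonical name or a synonym, tokenized (names are designed so
        whitespace split == tokenizer output)."""
        options = [name_of[cid]] + syns_of[cid]
        return rng.choice(options).split()

    def edge_sentence(src: str, verb: str, tgt: str,
                      style: str) -> tuple[list[str],
                                           list[tuple[int, int, str, str]]]:
        """Build tokens asserting src --verb--> tgt; returns mentions."""
        s_toks = surface_tokens(src)
        t_toks = surface_tokens(tgt)
        if style == "passive":
            # "T is VERBed by S" : direction reversed back to src->tgt
            toks = t_toks + ["is", _past(verb), "by"] + s_toks + ["."]
            ments = [(0, len(t_toks), tgt, _etype(tgt)),
                     (len(t_toks) + 3, len(t_toks) + 3 + len(s_toks),
                      src, _etype(src))]
        else:
            verb_form = verb + ("es" if verb.endswith(("s", "x", "z", "ch",
                                                       "sh")) else "s")
            toks = s_toks + [verb_form] + t_toks + ["."]
            ments = [(0, len(s_toks), src, _etype(src)),
                     (len(s_toks) + 1, len(s_toks) + 1 + len(t_toks),
                      tgt, _etype(tgt))]
        return toks, ments

    def _etype(cid: str) -> str:
        return {"D": DRUG, "P": PROTEIN, "S": SIDE_EFFECT}[cid[0]]

    def _past(verb: str) -> str:
        if verb.endswith("e"):
            return verb + "d"
        return verb + "ed"

    def plant_chain(c: int, depth: int, recoverable: bool,
                    effect_term: str | None = None,
                    neutral_first_edge: bool = False) -> None:
        did = f"D{c:03d}"
        name, syns = namer.drug(c)
        register(drugs, did, name, syns)
        pids = []
        for j in range(depth):
            pid = f"P{c:03d}{j}"
            pname, psyns = namer.protein(c, j)
            register(proteins, pid, pname, psyns)
            pids.append(pid)
        sid = f"S{c:03d}"
        sname, ssyns = namer.side_effect(c, effect_term)
        register(side_effects, sid, sname, ssyns)

        nodes = [did, *pids, sid]
        verbs = []
        for i in range(len(nodes) - 1):
            terminal = i == len(nodes) - 2
            if neutral_first_edge and i == 0:
                verb = rng.choice(_NEUTRAL_VERBS)
            elif terminal:
                verb = rng.choice(_NEUTRAL_VERBS + _DECREASE_VERBS
                                  + _INCREASE_VERBS)
            else:
                verb = rng.choice(_INCREASE_VERBS + _DECREASE_VERBS)
            verbs.append(verb)
            style = rng.choice(["active", "active", "passive"])
            toks, ments = edge_sentence(nodes[i], verb, nodes[i + 1], style)
            sentences.append((toks, ments,
                              [(nodes[i], verb, nodes[i + 1], False)]))
        chains.append(PlantedChain(
            chain_id=c, drug_id=did, protein_ids=tuple(pids),
            side_effect_id=sid, edge_verbs=tuple(verbs), depth=depth,
            label=_LABELS[c % 3], recoverable=recoverable))

    for c, depth in enumerate(depths):
        plant_chain(c, depth, recoverable=True)

    n_regular = len(depths)
    if with_distractors:
        # whole-chain distractors: filtered out downstream, not
        # counted as recoverable paths
        plant_chain(n_regular, 1, recoverable=False, effect_term="tumor")
        plant_chain(n_regular + 1, 1, recoverable=False,
                    neutral_first_edge=True)

        # sentence-level distractors on dedicated entities
        c = n_regular + 2
        did, (dn, ds) = f"D{c:03d}", namer.drug(c)
        register(drugs, did, dn, ds)
        pid, (pn, ps) = f"P{c:03d}0", namer.protein(c, 0)
        register(proteins, pid, pn, ps)

        # negated: extracted as a triple but flagged, excluded from graph
        verb = rng.choice(_DECREASE_VERBS)
        toks = dn.split() + ["does", "not", verb] + pn.split() + ["."]
        ments = [(0, len(dn.split()), did, DRUG),
                 (len(dn.split()) + 3, len(dn.split()) + 3 + len(pn.split()),
                  pid, PROTEIN)]
        sentences.append((toks, ments, [(did, verb, pid, True)]))

        # over-long gap: verb present but 8 tokens separate the entities
        verb2 = rng.choice(_INCREASE_VERBS)
        toks = dn.split() + _FILLER + [verb2 + "s"] + pn.split() + ["."]
        ments = [(0, len(dn.split()), did, DRUG),
                 (len(dn.split()) + 8, len(dn.split()) + 8 + len(pn.split()),
                  pid, PROTEIN)]
        sentences.append((toks, ments, []))

        # unknown verb: "examines" is not in the bio-verb lexicon
        toks = dn.split() + ["examines"] + pn.split() + ["."]
        ments = [(0, len(dn.split()), did, DRUG),
                 (len(dn.split()) + 1, len(dn.split()) + 1 + len(pn.split()),
                  pid, PROTEIN)]
        sentences.append((toks, ments, []))

    # ---- distribute sentences over documents --------------------------
    order = list(range(len(sentences)))
    rng.shuffle(order)
    buckets: list[list[int]] = [[] for _ in range(n_docs)]
    for pos, si in enumerate(order):
        buckets[pos % n_docs].append(si)

    documents: list[Document] = []
    for d in range(n_docs):
        pmid = str(10_000_000 + d)
        title = f"Synthetic report {d} on molecular findings"
        parts = []
        for rank, si in enumerate(buckets[d]):
            toks, ments, trips = sentences[si]
            text = " ".join(toks[:-1]) + "."
            text = text[0].upper() + text[1:]
            parts.append(text)
            sent_idx = rank + 1  # title occupies sentence index 0
            for (start, end, cid, etype) in ments:
                gt.mentions.append((pmid, sent_idx, start, end, cid, etype))
            for (s, v, t, neg) in trips:
                gt.triples.append((s, v, t, neg))
        abstract = " ".join(parts) if parts else "Findings were unremarkable."
        documents.append(Document(pmid=pmid, title=title, abstract=abstract))
        gt.sentence_counts[pmid] = len(parts) if parts else 1
    gt.chains = chains

    # ---- hierarchy: ROOT -> type branch -> family -> entity -----------
    hier_lines = ["ROOT\t-", "DRUGS\tROOT", "PROTEINS\tROOT",
                  "EFFECTS\tROOT"]
    for branch, rows in (("DRUGS", drugs), ("PROTEINS", proteins),
                         ("EFFECTS", side_effects)):
        for cid, _, _ in rows:
            fam = f"{branch}_FAM{int(cid[1:4]) // 2}"
            if f"{fam}\t{branch}" not in hier_lines:
                hier_lines.append(f"{fam}\t{branch}")
            hier_lines.append(f"{cid}\t{fam}")

    verbs_tsv = "\n".join(_read_packaged("bioverbs.tsv")) + "\n"

    return SyntheticCorpus(
        documents=documents,
        drug_lexicon_tsv=_lexicon_tsv(drugs),
        protein_lexicon_tsv=_lexicon_tsv(proteins),
        side_effect_lexicon_tsv=_lexicon_tsv(side_effects),
        verbs_tsv=verbs_tsv,
        hierarchy_tsv="\n".join(hier_lines) + "\n",
        ground_truth=gt,
    )
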