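"""Corpus ingestion: MEDLINE/PubMed XML parsing, sentence segmentation,
tokenization and part-of-speech tagging.

A corpus is an iterable of :class:`Document` objects, each holding the
PubMed identifier, title, abstract and (after :func:`segment_sentences`
and :func:`tag_sentence`) a list of tokenized, lemmatized sentences.

Two input dialects are supported: PubMed/MEDLINE XML
(``PubmedArticle/MedlineCitation/Article``) and a plain-text TSV dialect
with one ``PMID<TAB>TITLE<TAB>ABSTRACT`` record per line.  Documents can
be checkpointed to JSON-lines and read back without loss.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from lxml import etree

__all__ = [
    "Document",
    "Sentence",
    "tokenize",
    "parse_medline_xml",
    "parse_tsv_corpus",
    "segment_sentences",
    "tag_sentence",
    "RuleTagger",
    "get_tagger",
    "write_jsonl",
    "read_jsonl",
    "documents_to_xml",
]


@dataclass
class Sentence:
    """One sentence of a document with parallel token/lemma/POS lists.

    ``pos_tags`` uses a coarse tagset: ``VERB`` (a recognized verb
    inflection), ``NOUN`` (open-class default), ``OTHER`` (function
    words, auxiliaries, punctuation).
    """

    doc_pmid: str
    index: int
    tokens: list[str]
    lemmas: list[str] = field(default_factory=list)
    pos_tags: list[str] = field(default_factory=list)
    from_title: bool = False

    def __post_init__(self) -> None:
        if self.lemmas and len(self.lemmas) != len(self.tokens):
            raise ValueError("lemmas and tokens must be parallel")
        if self.pos_tags and len(self.pos_tags) != len(self.tokens):
            raise ValueError("pos_tags and tokens must be parallel")

    def to_dict(self) -> dict:
        return {
            "doc_pmid": self.doc_pmid,
            "index": self.index,
            "tokens": self.tokens,
            "lemmas": self.lemmas,
            "pos_tags": self.pos_tags,
            "from_title": self.from_title,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sentence":
        return cls(
            doc_pmid=d["doc_pmid"],
            index=d["index"],
            tokens=list(d["tokens"]),
            lemmas=list(d.get("lemmas", [])),
            pos_tags=list(d.get("pos_tags", [])),
            from_title=bool(d.get("from_title", False)),
        )


@dataclass
class Document:
    """One abstract: PubMed id, title, abstract text and its sentences."""

    pmid: str
    title: str
    abstract: str
    sentences: list[Sentence] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "sentences": [s.to_dict() for s in self.sentences],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Document":
        return cls(
            pmid=d["pmid"],
            title=d["title"],
            abstract=d["abstract"],
            sentences=[Sentence.from_dict(s) for s in d.get("sentences", [])],
        )


# --------------------------------------------------------------------------
# Tokenization and sentence segmentation
# --------------------------------------------------------------------------

# Word tokens keep internal hyphens and slashes so biomedical names such
# as "gastrin-17", "NF-κB" or "p38" survive as single tokens; everything
# else (punctuation) becomes a one-character token.
_TOKEN_RE = re.compile(r"\w+(?:[-/’']\w+)*|[^\w\s]", re.UNICODE)

# Abbreviations whose trailing period never ends a sentence.
_ABBREVIATIONS = (
    "e.g.", "i.e.", "et al.", "etc.", "vs.", "cf.", "Fig.", "fig.",
    "approx.", "ca.", "resp.", "Dr.", "St.",
)

_BOUNDARY_RE = re.compile(r"([.?!])(\s+)(?=[A-Z0-9])")


def tokenize(text: str) -> list[str]:
    """Split text into word and punctuation tokens.

    Hyphenated/slashed biomedical names stay single tokens.
    """
    return _TOKEN_RE.findall(text)


def _split_sentences(text: str) -> list[str]:
    """Period/question/exclamation followed by whitespace and an
    uppercase letter or digit ends a sentence, unless the period belongs
    to a known abbreviation.  Falls back to the whole text when no
    boundary is found."""
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end(1)
        prefix = text[:end]
        if any(prefix.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        pieces.append(text[start:end].strip())
        start = m.end(2)
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [p for p in pieces if p] or ([text.strip()] if text.strip() else [])


def segment_sentences(doc: Document, include_title: bool = True) -> Document:
    """Return a copy of *doc* with ``sentences`` populated.

    Title sentences (flagged ``from_title``) precede abstract sentences
    when *include_title* is set; abstract sentences always cover the
    abstract text in order.
    """
    sentences: list[Sentence] = []
    idx = 0
    if include_title and doc.title.strip():
        for raw in _split_sentences(doc.title):
            toks = tokenize(raw)
            if toks:
                sentences.append(
                    Sentence(doc.pmid, idx, toks, from_title=True))
                idx += 1
    for raw in _split_sentences(doc.abstract):
        toks = tokenize(raw)
        if toks:
            sentences.append(Sentence(doc.pmid, idx, toks))
            idx += 1
    return replace(doc, sentences=sentences)


# --------------------------------------------------------------------------
# POS tagging (pluggable contract)
# --------------------------------------------------------------------------

_BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am"}
_AUX_FORMS = {"do", "does", "did", "have", "has", "had", "will", "would",
              "can", "could", "may", "might", "shall", "should", "must"}
_FUNCTION_WORDS = _BE_FORMS | _AUX_FORMS | {
    "a", "an", "the", "this", "that", "these", "those",
    "of", "in", "on", "at", "by", "to", "for", "with", "from", "into",
    "and", "or", "but", "nor", "neither", "either", "as", "than",
    "not", "no", "never", "hardly", "scarcely", "without", "n't",
    "it", "its", "we", "our", "their", "which", "who", "whose",
    "via", "through", "between", "among", "during", "after", "before",
    "both", "also", "only", "such", "then", "thus", "however",
}

# Small irregular verb table: inflected form -> lemma.
_IRREGULAR_VERBS = {
    "led": "lead", "became": "become", "become": "become",
    "rose": "rise", "risen": "rise", "gave": "give", "given": "give",
    "shown": "show", "showed": "show", "arose": "arise", "arisen": "arise",
    "underwent": "undergo", "undergone": "undergo",
    "found": "find", "bound": "bind", "gives": "give",
}


def _inflections(lemma: str) -> list[str]:
    """Regular English inflections of a verb lemma: 3sg, past/participle,
    gerund."""
    forms = [lemma]
    if re.search(r"(s|x|z|ch|sh)$", lemma):
        forms.append(lemma + "es")
    elif re.search(r"[^aeiou]y$", lemma):
        forms.append(lemma[:-1] + "ies")
    else:
        forms.append(lemma + "s")
    if lemma.endswith("e"):
        forms.append(lemma + "d")
        forms.append(lemma[:-1] + "ing")
    elif re.search(r"[^aeiou]y$", lemma):
        forms.append(lemma[:-1] + "ied")
        forms.append(lemma + "ing")
    else:
        forms.append(lemma + "ed")
        forms.append(lemma + "ing")
    return forms


class RuleTagger:
    """Deterministic lexicon + suffix rule tagger.

    Tokens matching an inflection of a known verb lemma are tagged
    ``VERB`` and lemmatized to it; closed-class function words and
    punctuation are ``OTHER``; everything else is ``NOUN``.  Runs fully
    offline with no model download.
    """

    name = "rule"

    def __init__(self, verb_lemmas: Iterable[str] = ()) -> None:
        self._form_to_lemma: dict[str, str] = {}
        for lemma in sorted({v.lower() for v in verb_lemmas}):
            for form in _inflections(lemma):
                self._form_to_lemma.setdefault(form, lemma)
        for form, lemma in _IRREGULAR_VERBS.items():
            self._form_to_lemma.setdefault(form, lemma)

    def verb_lemma(self, token: str) -> str | None:
        return self._form_to_lemma.get(token.lower())

    def tag(self, tokens: Sequence[str]) -> tuple[list[str], list[str]]:
        lemmas: list[str] = []
        pos: list[str] = []
        for tok in tokens:
            low = tok.lower()
            verb = self._form_to_lemma.get(low)
            if verb is not None and low not in _FUNCTION_WORDS:
                lemmas.append(verb)
                pos.append("VERB")
            elif low in _BE_FORMS:
                lemmas.append("be")
                pos.append("OTHER")
            elif low in _FUNCTION_WORDS or not any(c.isalnum() for c in tok):
                lemmas.append(low)
                pos.append("OTHER")
            else:
                lemmas.append(low)
                pos.append("NOUN")
        return lemmas, pos


def get_tagger(name: str, verb_lemmas: Iterable[str] = ()):
    """Resolve a tagger by configuration name.

    ``rule`` is the offline default; adapters for external statistical
    taggers can be registered here.  Unknown names raise ``ValueError``.
    """
    if name == "rule":
        return RuleTagger(verb_lemmas)
    raise ValueError(f"unknown tagger: {name!r}")


def tag_sentence(s: Sentence, tagger) -> Sentence:
    """Return a copy of *s* with lemmas and POS tags filled in."""
    lemmas, pos = tagger.tag(s.tokens)
    return replace(s, lemmas=lemmas, pos_tags=pos)


# --------------------------------------------------------------------------
# MEDLINE XML / TSV parsing
# --------------------------------------------------------------------------

def parse_medline_xml(stream: IO[bytes] | str) -> Iterator[Document]:
    """Stream ``Document`` objects out of PubMed/MEDLINE XML.

    One document is produced per ``PubmedArticle`` record that carries a
    non-empty abstract; records lacking an abstract are skipped silently
    and records lacking a PMID are skipped with a warning.  Malformed
    XML raises ``lxml.etree.XMLSyntaxError`` (which reports the parse
    position).
    """
    for _, elem in etree.iterparse(stream, tag="PubmedArticle"):
        pmid = elem.findtext(".//MedlineCitation/PMID")
        title = elem.findtext(".//Article/ArticleTitle") or ""
        abstract_parts = [
            (t.text or "") for t in elem.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p).strip()
        elem.clear()
        if pmid is None or not pmid.strip():
            warnings.warn("PubmedArticle without PMID skipped")
            continue
        if not abstract:
            continue
        yield Document(pmid=pmid.strip(), title=title.strip(),
                       abstract=abstract)


def parse_tsv_corpus(stream: IO[str] | Iterable[str]) -> Iterator[Document]:
    """Plain-text dialect: one ``PMID<TAB>TITLE<TAB>ABSTRACT`` per line."""
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated "
                             f"fields, got {len(parts)}")
        pmid, title, abstract = (p.strip() for p in parts)
        if not abstract:
            continue
        yield Document(pmid=pmid, title=title, abstract=abstract)


def documents_to_xml(docs: Iterable[Document]) -> bytes:
    """Serialize documents back to a minimal PubmedArticleSet (round-trip
    counterpart of :func:`parse_medline_xml`)."""
    root = etree.Element("PubmedArticleSet")
    for doc in docs:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = doc.pmid
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = doc.title
        abstract = etree.SubElement(article, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = doc.abstract
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_jsonl(docs: Iterable[Document], stream: IO[str]) -> int:
    """Dump one Document per line; returns the number written."""
    n = 0
    for doc in docs:
        stream.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")
        n += 1
    return n


def read_jsonl(stream: IO[str] | Iterable[str]) -> Iterator[Document]:
    for line in stream:
        if line.strip():
            yield Document.from_dict(json.loads(line))
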