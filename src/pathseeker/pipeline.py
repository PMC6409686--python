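"""End-to-end mining pipeline.

Convenience driver chaining the stages: segment and tag documents,
recognize entity mentions, extract relation triples, assemble the
knowledge graph, enumerate and filter drug→protein^k→side-effect paths,
and rank them with the combined scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import Document, RuleTagger, segment_sentences, tag_sentence
from .graph_paths import (KnowledgeGraph, KnowledgePath, build_graph,
                          enumerate_paths, filter_significant,
                          DEFAULT_EFFECT_TERMS)
from .lexicon_ner import EntityMention, Lexicon, match_entities
from .ranking_eval import (LocalFrequencyTable, RankedPath, RankingWeights,
                           make_scorer, rank_paths)
from .relation_extraction import (BioVerbLexicon, RelationTriple,
                                  extract_relations, DEFAULT_WINDOW)
from .semantic_similarity import CoalsModel, ConceptHierarchy, train_coals

__all__ = ["PipelineResult", "run_extraction", "collapse_mentions",
           "rank_pipeline_paths"]


@dataclass
class PipelineResult:
    documents: list[Document]
    mentions: list[EntityMention]
    triples: list[RelationTriple]
    graph: KnowledgeGraph
    paths: list[KnowledgePath] = field(default_factory=list)
    ranked: list[RankedPath] = field(default_factory=list)


def run_extraction(
    documents: list[Document],
    lexicons: dict[str, Lexicon],
    verbs: BioVerbLexicon,
    window: int = DEFAULT_WINDOW,
    include_title: bool = True,
    drug_whitelist: set[str] | None = None,
    effect_terms=DEFAULT_EFFECT_TERMS,
    depths: tuple[int, ...] = (1, 2, 3),
) -> PipelineResult:
    """Mine documents end to end: mentions → triples → graph → filtered
    candidate paths (pooled over the requested depths)."""
    tagger = RuleTagger(verbs.lemmas)
    docs = []
    mentions: list[EntityMention] = []
    triples: list[RelationTriple] = []
    for doc in documents:
        doc = segment_sentences(doc, include_title=include_title)
        doc.sentences = [tag_sentence(s, tagger) for s in doc.sentences]
        docs.append(doc)
        for s in doc.sentences:
            ms = match_entities(s, lexicons)
            mentions.extend(ms)
            triples.extend(extract_relations(s, ms, verbs, window=window))
    graph = build_graph(triples, drug_whitelist=drug_whitelist)
    names = {}
    for lex in lexicons.values():
        for entry in lex:
            names[(entry.canonical_id, entry.entity_type)] = (
                entry.canonical_name)
    paths: list[KnowledgePath] = []
    for k in depths:
        paths.extend(enumerate_paths(graph, k))
    paths = filter_significant(paths, effect_terms=effect_terms,
                               side_effect_names=names)
    return PipelineResult(documents=docs, mentions=mentions, triples=triples,
                          graph=graph, paths=paths)


def collapse_mentions(result: PipelineResult) -> list[list[str]]:
    """Tokenized sentences with entity mentions replaced by their
    canonical ids — the input representation for COALS training."""
    by_sentence: dict[tuple[str, int], list[EntityMention]] = {}
    for m in result.mentions:
        by_sentence.setdefault((m.pmid, m.sentence_index), []).append(m)
    out: list[list[str]] = []
    for doc in result.documents:
        for s in doc.sentences:
            ms = sorted(by_sentence.get((doc.pmid, s.index), []),
                        key=lambda m: m.start)
            toks: list[str] = []
            pos = 0
            for m in ms:
                toks.extend(t.lower() for t in s.tokens[pos:m.start])
                toks.append(m.canonical_id)
                pos = m.end
            toks.extend(t.lower() for t in s.tokens[pos:])
            out.append(toks)
    return out


def rank_pipeline_paths(
    result: PipelineResult,
    hierarchy: ConceptHierarchy | None = None,
    coals: CoalsModel | None = None,
    weights: RankingWeights = RankingWeights(),
    coals_window: int = 4,
    coals_dim: int | None = None,
) -> list[RankedPath]:
    """Train COALS on the mined corpus (unless a model is supplied) and
    rank the candidate paths with the combined scorer."""
    if coals is None:
        sentences = collapse_mentions(result)
        if any(sentences):
            coals = train_coals(sentences, window=coals_window,
                                dim=coals_dim)
    freq = LocalFrequencyTable(result.paths)
    scorer = make_scorer(coals, hierarchy, freq, weights)
    result.ranked = rank_paths(result.paths, scorer)
    return result.ranked
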