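# Methods

This note documents the models and procedures implemented in
`pathseeker`, the defaults they use, and the design choices made where
several readings were defensible.

## Problem setting

Given a corpus of biomedical abstracts and dictionaries of drugs,
proteins and side effects, the pipeline extracts three relation types —
drug→protein, protein→protein, protein→side-effect — and composes them
into candidate mechanistic paths `drug → protein₁ … proteinₖ → side
effect` with k = 1..3 bridging proteins (the *depth* of the path).
Proteins are the mediating layer because most drug action and most
adverse events are protein-mediated. The output is a ranked list of
paths: each is a hypothesis, not an established mechanism, and the
ranking exists to put the hypotheses most consistent with the literature
at the top.

## Pre-processing

* **Parsing.** MEDLINE/PubMed XML is read with a streaming
  (`iterparse`) parser; one document per `PubmedArticle` with a
  non-empty abstract. Records without an abstract are skipped; records
  without a PMID are skipped with a warning. A plain
  `PMID<TAB>TITLE<TAB>ABSTRACT` dialect is accepted for convenience.
* **Sentence segmentation** is a period/question/exclamation boundary
  followed by whitespace and an uppercase letter or digit, with a small
  abbreviation list ("e.g.", "i.e.", "et al.", …) suppressing false
  splits, and a whole-text fallback when no boundary is found. By
  default titles are mined as well as abstracts (a flag disables this);
  title sentences are marked so corpus statistics can exclude them.
* **Tokenization** splits on whitespace and punctuation but keeps
  hyphen/slash-internal names ("p38", "NF-κB", "gastrin-17") as single
  tokens, since entity dictionaries are full of such forms. Case is
  preserved in storage; each matching stage decides its own folding.
* **POS tagging** is a pluggable contract. The default is a
  deterministic lexicon + suffix rule tagger: any token matching a
  regular (or listed irregular) inflection of a known biomedical verb
  lemma is `VERB` with that lemma; closed-class function words,
  auxiliaries and punctuation are `OTHER`; everything else is `NOUN`.
  This coarse tagset is exactly what the extraction rules consume, runs
  with no model download, and is reproducible bit-for-bit. An adapter
  slot (`get_tagger`) exists for wiring in an external statistical
  tagger where one is available.

## Named entity recognition

NER is exact dictionary matching of 1/2/3-gram token windows against an
inverted synonym index — a deliberate precision-over-recall choice for
this task, where a wrong entity poisons every path through it. Details:

* matching is case-insensitive (configurable) with surfaces preserved;
* overlaps resolve longest-match-first, ties to the leftmost start, so
  "little gastrin 1" never also yields a nested "gastrin" mention;
* within one entity type a synonym maps to exactly one canonical id
  (first-wins with a warning on collision); synonym variants of one
  concept (gastrin-17 / g17 / little gastrin 1) are merged by mapping
  them to a single canonical id;
* the same surface on the same span in two lexicons yields one mention
  by a configurable type priority (PROTEIN > DRUG > SIDE_EFFECT by
  default — gene/drug homonyms are more often gene mentions in this
  corpus genre).

## Relation extraction rules

A directed triple `source —verb→ target` is asserted from a single
sentence when all of the following hold:

1. **Structure**: the verb token lies strictly between the two mention
   spans (entity–verb–entity).
2. **Verb lexicon**: the verb's lemma is in the biomedical verb
   lexicon. Each lemma carries a polarity: INCREASE (activate,
   stimulate, induce, …), DECREASE (inhibit, block, reduce, …) or
   NEUTRAL (associate, observe, correlate, …). The bundled lexicon has
   73 lemmas curated for this package; callers can supply their own
   larger list as TSV.
3. **Distance**: at most 6 tokens (the window; configurable) separate
   the two mention spans. The bound is interpreted as the count of
   tokens strictly between the spans — the most permissive reading —
   and the connecting verb counts toward it.
4. **Negation**: a cue ("not", "no", "never", "hardly", "scarcely",
   "n't", "neither", "nor", "without") within the 3 tokens before the
   verb flags the triple as negated. Negated triples are retained and
   flagged, but excluded from graph construction by default — the
   conservative disposal, configurable via `include_negated`.
5. **Direction**: active voice points first→second mention; passive
   voice (a be/auxiliary form within 2 tokens before a past-participle
   verb form) reverses it, so "A is activated by B" and "B activates A"
   produce the same directed triple.

Every qualifying verb between a pair yields its own triple (multi-verb
links such as "inhibit, block" are common and informative). Only the
type pairs drug→protein, protein→protein, protein→side-effect are kept,
so a drug can never be a target and side effects are always terminal.
All rules fire on POS/token patterns alone; no dependency parser is
required, which keeps extraction deterministic and offline.

## Graph and path enumeration

Triples merge into a typed directed graph; parallel triples (same
source, target) accumulate verbs, polarities and a support count equal
to the number of supporting triples. An optional drug whitelist
restricts the graph to a study's drugs of interest. Path enumeration is
a depth-bounded DFS producing exactly the simple paths
drug →(k protein hops)→ side effect, k = 1..3, in lexicographic node-id
order (deterministic and order-independent of the input triples).
Protein→protein edges are traversed only in their asserted direction —
the voice rule exists precisely to orient them — and no de-duplication
is performed across depths.

Two filters then remove non-side-effect paths:

* **Intended-effect endpoints**: a path whose side-effect name contains
  "tumor", "tumour", "cancer", "carcinoma" or "neoplasm" describes the
  drug doing its job, not an adverse event.
* **Significance**: every edge except the terminal protein→side-effect
  edge must carry at least one INCREASE/DECREASE verb (the terminal
  edge may be merely associative). The predicate is configurable since
  "represents a change" admits stricter readings.

## Ranking

For a path `v₀ … vₙ` ending in side effect SE:

```
EntityPairWeight(vᵢ, vᵢ₊₁) = α·COALS(vᵢ, vᵢ₊₁)
                           + β·LocalFreq(vᵢ, vᵢ₊₁, SE)/MaxLocalFreq(SE)
                           + γ·Hier(vᵢ, vᵢ₊₁)
PathScore = (1/n) Σᵢ EntityPairWeight(vᵢ, vᵢ₊₁)
```

Defaults α, β, γ = 0.3, 0.4, 0.3; weights must be non-negative and are
renormalized to sum to 1 with a warning otherwise. With all components
in [0, 1] every pair weight and path score is in [0, 1]. Ranking is a
stable descending sort with lexicographic (drug, proteins, side-effect)
tie-breaks for determinism. Ranking is pooled across depths 1–3.

* **COALS** (Correlated Occurrence Analogue to Lexical Semantics).
  Co-occurrence counts use a ramped window of 4 (a neighbor at distance
  d contributes weight 5 − d; windows do not cross sentences). Counts
  are then normalized cell-wise to the correlation
  `(T·w_ab − r_a·c_b) / √(r_a(T−r_a)·c_b(T−c_b))`, negatives zeroed,
  positives square-rooted. Columns may be truncated to the `dim`
  most frequent terms *before* normalization (ties lexicographic); no
  SVD step is applied, keeping the model exactly reproducible at
  desk-scale corpora. Similarity of two terms is the Pearson
  correlation of their vectors clamped to [0, 1]; unseen terms and
  all-zero vectors score 0. Entity mentions are collapsed to their
  canonical ids before counting so multi-token entities have
  well-defined vectors.
* **LocalFreq / MaxLocalFreq.** LocalFreq(vᵢ, vⱼ, SE) is the number of
  occurrences of the edge among all candidate paths that end in SE;
  MaxLocalFreq(SE) is the largest such count. A side effect with no
  counted pairs contributes 0 rather than dividing by zero.
* **Hierarchy similarity.** Wu–Palmer over a rooted is-a DAG supplied
  as child→parent TSV (root depth 1, depth = shortest root chain):
  `2·depth(lcs)/(depth(a)+depth(b))`, with the deepest common ancestor
  as LCS (lexicographic tie-break). Wu–Palmer was chosen because it is
  bounded, parameter-free and computable on any supplied taxonomy; a
  rescaled path-length measure is available behind `method="path"`.
  Entities not mapped into the hierarchy score 0.

Three single-component baselines support comparison: mean normalized
edge support ("co-occurrence"; implemented as support divided by the
maximum edge support, the reading that needs no statistic beyond the
graph itself), COALS-only, and hierarchy-only. The latter two are
definitionally the combined scorer with weights (1,0,0) and (0,0,1),
and the test suite asserts bit-exact agreement.

## Evaluation

Precision-at-k is `|{i ≤ k : label_i ∈ truth}| / k` over a ranked,
labelled path list. Two truth conventions are used: strict (TYPE1 only
correct) and lenient (TYPE1 ∪ TYPE2 correct, TYPE3 incorrect). The
package bundles a 20-path expert-labelled reference ranking (6 TYPE1, 7
TYPE2, 7 TYPE3) whose strict P@5/P@10/P@15/P@20 are 0.60/0.60/0.40/0.30
and lenient 0.80/0.80/0.73/0.65; 13 of 20 paths (65 %) are plausible
under the lenient convention. These values are recomputed, never stored,
by `scripts/acceptance.py` and the acceptance tests.

## Synthetic data generator

`generate_corpus(n_docs, n_chains, depth_mix, seed)` emulates the study
conditions at desk scale: chains with a 0.4/0.3/0.3 mix of depths 1–3
are planted as entity–verb–entity template sentences (roughly one third
passive), shuffled into `n_docs` abstracts, with entity names designed
to stress the matcher (hyphen+digit tokens, multi-token names, 3-gram
synonyms, case variation at sentence starts). Distractors each violate
exactly one rule: a negated assertion ("does not inhibit"), an
over-long 8-token gap, a verb outside the lexicon, a chain ending in a
"tumor" name, and a chain whose first edge is only associative. The
generator returns the exact ground truth (mention spans, triples,
chains) and writes MEDLINE XML plus all lexicon/hierarchy TSVs;
regeneration with the same seed is byte-identical.

What the generator does **not** emulate: real PubMed language
(free word order, anaphora, coordination, apposition), ambiguous or
misspelled entity names, cross-sentence relations, and realistic
frequency distributions. Passing the end-to-end recovery test therefore
shows the pipeline implements its own rules exactly — not that the rules
themselves achieve any particular precision/recall on real text.

## Problem sizes and numerical choices

The test and acceptance runs use corpora of 10–25 abstracts with 8–25
planted chains and ~30-node random graphs — sizes at which brute-force
oracles (exhaustive rule checking, exhaustive DFS, term-by-term COALS
correlation, exhaustive LCS search) are feasible and exact. COALS
comparisons against the oracle are at 1e-10; ranking-baseline identities
are exact (`==`). Degenerate inputs: empty corpora raise, an empty verb
lexicon yields zero triples, unknown similarity terms score 0 with a
warning, and MaxLocalFreq = 0 zeroes the frequency term.

## Known limitations

* Dictionary NER cannot find entities absent from the lexicons, and
  exact matching misses morphological variants not listed as synonyms.
* POS-pattern voice/negation detection misses constructions a
  dependency parser would catch (long-range negation, reduced relative
  clauses); the rule windows (3 tokens for negation cues, 2 for
  passive auxiliaries) are heuristics.
* Single-sentence extraction ignores cross-sentence and coreferential
  evidence.
* The bundled 73-verb lexicon is a curated subset of the hundreds of
  verbs used in biomedical prose; recall on real corpora improves with
  a larger list supplied at run time.
* Corpus-scale statistics (millions of abstracts, thousands of pairs)
  are out of scope for the bundled tests, which operate at desk scale
  by design.
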