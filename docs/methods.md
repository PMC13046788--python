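# Methods

This note documents the models, rules and parameter choices behind
`phenogauge`, and what its synthetic-data tests do and do not establish
about behaviour on real cohorts.

## Evaluation model

A case is a phenopacket v2 document: a subject (sex, age at last
examination), a list of phenotypic features — HPO terms observed or
explicitly excluded, optionally with onset ages — and a single
gold-standard diagnosis carried as an OMIM, Orphanet or Mondo identifier.
A method's output for a case is an ordered list of candidate diagnoses;
position *i* is rank *i* + 1, and the order is the method's assertion, so
duplicates and ungrounded items keep their slots (compacting the list
would silently inflate accuracy).

Scoring routes everything through Mondo, the disease ontology that
integrates OMIM and Orphanet nomenclatures:

- **Alignment.** The gold identifier is aligned to Mondo through
  exact-match equivalence mappings (SSSOM `skos:exactMatch` rows only;
  broad/narrow mappings are rejected because the rule requires genuine
  equivalence, and one-to-many exact matches are a load error). A case
  whose gold cannot be aligned is flagged unevaluable and excluded from
  denominators, with the exclusion counted and reported — silently keeping
  such cases would conflate tool error with mapping gaps.
- **Correctness.** A predicted Mondo term `d` is correct for aligned gold
  `g` iff `d = g` or `g` lies within `rollup_distance` is-a edges below
  `d`. Only is-a edges participate: disease grouping in Mondo is is-a
  based. The recorded route distinguishes identity (`exact_id`), identity
  after cross-nomenclature alignment (`equivalence`), and subsumption
  (`rollup`).
- **Directionality.** The roll-up credits a *general* prediction for a
  *specific* gold, not the reverse. Predicting "geleophysic dysplasia 2"
  when the gold is the grouping "geleophysic dysplasia" asserts an
  unsupported genetic subtype; the default rule scores it incorrect. A
  `symmetric_rollup` flag reverses this for sensitivity analysis.
- **`rollup_distance` (default 1).** "Closeness" of the descendant
  relation is an edge-distance bound. The canonical
  subtype-under-grouping configuration sits one edge apart, and a bounded
  default prevents credit for arbitrarily general answers ("genetic
  disease" subsumes almost everything at unbounded distance). The bound is
  a config/CLI parameter; a negative CLI value means unbounded.

Top-k accuracy over a cohort is the fraction of evaluable cases whose
first correct item has rank ≤ k; by construction Top-1 ≤ Top-3 ≤ Top-10.
Paired comparison of two methods uses McNemar's test on Top-1 discordant
counts `b` (A correct, B not) and `c` (the reverse): the exact two-sided
binomial test when `b + c < 25`, where the χ² approximation is poor, and
χ² = (b−c)²/(b+c) on 1 df without continuity correction otherwise — at
the scale where the branch switches the two are practically
indistinguishable. No multiple-testing correction is applied by default;
callers running many pairwise comparisons can Bonferroni-correct the
returned p-values.

## Grounding

Free-text items are grounded in two stages over the non-obsolete disease
terms' labels and synonyms:

1. **Exact**: the normalized item equals a normalized label or synonym.
   Normalization case-folds, applies NFKC, unifies dashes and apostrophes,
   strips surrounding punctuation, collapses whitespace, and removes a
   trailing parenthetical qualifier ("… (BBS)") for matching only. Exact
   hits score 1.0 and the similarity scorer is never consulted.
2. **Similarity**: otherwise the highest-scoring term under the configured
   scorer is accepted iff its score reaches `threshold` (default 0.80).
   The default scorer is the max of plain normalized edit similarity
   (1 − Levenshtein/max length) and its token-sort variant. Token-sorting
   makes word order irrelevant, but on its own it is brittle: a typo in a
   token's first letter can flip the sort order and collapse the score
   (e.g. "uysplasia" sorts after "rhizomelic" while "dysplasia" sorts
   before it), so the composite takes whichever view scores higher —
   the same approach fuzzy-matching libraries use in their composite
   ratios. Both components are also registered individually, and any
   callable can be registered under a scorer id (e.g. an embedding-based
   matcher); the pipeline treats the scorer as interchangeable.

Ties — one string naming several terms, or equal similarity scores —
resolve deterministically to the lexicographically smallest CURIE and are
flagged on the result. The 0.80 threshold admits single-typo variants of
multi-word disease names (≈0.95 similarity at typical name lengths) while
rejecting unrelated strings; it is exposed in config and on the CLI.
Ungrounded items are kept in place and scored incorrect: a clinician
reading the output sees those items. Acronym-only inputs ground only if
the ontology carries the acronym as a synonym; no expansion dictionary is
invented.

## Prompt generation

Prompts are rendered deterministically from a template: a preamble that
explicitly requests a numbered list of diagnoses (one per line, most
likely first — closing the loop with the response parser), a demographic
sentence (sex, disease onset, age at last examination; absent values are
omitted, never placeholdered), the observed findings with each HPO label
exactly once, and — only when something was ruled out — a single negated
block ("The following findings were explicitly ruled out:"), which is less
ambiguous for humans and parsers than per-sentence negation. When observed
features carry distinct onset ages, findings are grouped into per-age
lists. Identifiers never appear in prompt text; the narrative carries
labels only. Ages are stored as ISO-8601 durations verbatim and rendered
to words only here ("P4Y2M" → "4-year, 2-month-old"; "P0D" → "newborn").
The exact wording is a parameter (YAML-overridable per model); the
structure is the tested contract.

## Response parsing

Free-text parsing accepts numbered ("1.", "2)", "3:", "Rank 4:") and
bulleted ("-", "*", "•") lines, strips enumeration markers and trailing
punctuation, and treats a non-blank unmarked line directly after a list
item as a continuation of that item (models wrap long lines). Parenthetical
qualifiers are kept whole; grounding handles synonyms. Unparseable text
yields an empty differential plus a warning record, never an exception.
Identifier mode reads one CURIE per line with an optional tab-separated
score column, preserving order.

## Synthetic data: what it emulates and what it does not

`synthcohort` builds a toy universe whose *structure* matches the real
benchmark inputs: a two-level disease DAG (grouping terms with
genetic-subtype leaves, mirroring genetically heterogeneous diseases),
exact mappings pairing each leaf with an OMIM-style identifier (so scoring
must exercise the equivalence route), a phenotype DAG with three
organ-system roots for stratification, and per-grouping phenotype profiles
shared by subtypes. Synthetic identifiers use reserved prefixes (MONDOX:,
OMIMX:) and the reserved HP:9xxxxxx number range so accidental mixing with
real ontologies is detectable while still satisfying the HP CURIE pattern.

Default cohort conditions target the real cohort's phenotyping depth:
10–19 disease-associated terms plus 0–3 off-profile noise terms per case
(mean ≈ 16 observed terms, the published per-case average; totals stay
within the real data's 1–50 range), 0–2 excluded terms, equal sex
probabilities, onset between birth and 12 years with examination 1–10
years later. Simulated responders place the gold label at a rank drawn
from an explicit distribution and fill other slots with other diseases'
labels; knobs emit the grouping label instead (exercising roll-up), a
one-letter typo (exercising similarity grounding), or ungroundable
gibberish fillers (emulating out-of-vocabulary response items). One master
seed fans out to per-stage child generators so stages re-run independently
and the whole chain is bit-reproducible.

What passing tests on this world do **not** show: real LLM outputs are
messier than the mock dialects; real Mondo/HPO graphs are deep,
multi-parent and release-dependent (results sensitive to ontology release
are expected to vary, not reproduce bit-exact); real disease names collide
and overlap lexically far more than the generated ones; and synthetic
phenotype profiles ignore term frequencies and co-occurrence. The
synthetic cohort validates the *pipeline arithmetic* — parsing, grounding
precedence, roll-up, rank bookkeeping, test statistics — not diagnostic
difficulty.

## Numerical and degenerate-input choices

- Top-k over an empty or fully unevaluable set raises rather than report
  0/0; grounding coverage of an empty list is reported absent (`None`),
  not 0.
- Descendant queries include the term itself at distance 0 and are
  monotone in the distance bound.
- The exact McNemar branch uses the two-sided binomial at p = ½, which at
  that symmetric null equals doubling the smaller tail (capped at 1);
  `b + c = 0` returns p = 1 with an absent statistic.
- Term-count stratification uses inclusive bins {≤5, 6–10, 11–20, 21–50}
  on observed (non-excluded) term counts; 0-term cases fall in ≤5, cases
  outside every bin land in an explicit `unbinned` bucket. Organ
  stratification likewise considers observed features only — an excluded
  finding is evidence *against* involvement of that system.
- Cohort reading orders cases lexicographically by case id (independent of
  filesystem enumeration), collects per-file failures instead of dropping
  them, and rejects duplicate case ids.
- Phenopacket v1 documents are rejected with a versioned error; only v2
  field names are accepted.

## Problem sizes

The test suite exercises toy ontologies up to ~50 nodes against brute-force
oracles, cohorts of 10–100 cases for structural checks, and one 5000-case
full-chain run for parameter recovery (a responder with true Top-1 0.30 is
recovered within ±0.02, about three standard errors). The acceptance
script simulates 5213 cases — the real cohort's size — over a 30-grouping,
90-subtype disease universe; the full double run (two responders through
the complete chain) takes well under a minute on one CPU.

## Known limitations

- Grounding is list-item-shaped; no NER inside long prose.
- Everything routes through Mondo; no direct OMIM/Orphanet grounding.
- Multi-diagnosis phenopackets are not modelled: exactly one gold
  diagnosis per case (the first solved interpretation wins).
- The stage-2 scorer is lexical by default; semantically related but
  lexically distant names ("Riley-Day syndrome" vs "hereditary sensory and
  autonomic neuropathy type III") ground only if the ontology carries the
  synonym. An embedding scorer can be plugged in behind the same
  interface.
- No token-budget handling or multilingual prompts.
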