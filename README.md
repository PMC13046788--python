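# phenogauge

Ontology-based benchmarking of phenotype-driven rare-disease differential
diagnosis.

## The problem

Tools that support rare-disease diagnosis — from classic phenotype-matching
software to large language models — return a ranked differential diagnosis
for a patient described by Human Phenotype Ontology (HPO) terms. Comparing
such tools fairly is hard: LLMs answer in free text with clinical disease
names ("geleophysic dysplasia"), specialist tools answer with precise
genetic identifiers ("OMIM:614185, geleophysic dysplasia 2"), and deciding
by hand whether a free-text answer "counts" is subjective and does not
scale to thousands of cases.

`phenogauge` implements a fully automated, ontology-based evaluation
pipeline for this comparison, aimed at researchers benchmarking diagnostic
decision support on GA4GH phenopacket cohorts:

1. **pheno_io** — read phenopacket v2 JSON case documents (observed and
   excluded HPO terms, demographics, gold OMIM/Orphanet/Mondo diagnosis)
   and parse ranked responses, free text or identifier lists.
2. **promptgen** — render each case into a deterministic clinical-narrative
   prompt requesting a numbered differential diagnosis.
3. **grounding** — map each free-text item to a Mondo disease term: exact
   label/synonym match first, then a threshold-gated string-similarity
   match (pluggable scorer).
4. **ontology_core / evaluation** — score each item with the ontology rule
   below, summarise cohorts as Top-k accuracy tables, stratify by organ
   system or phenotyping depth, and compare methods with a case-paired
   McNemar test.
5. **synthcohort** — generate toy ontologies, synthetic phenopacket cohorts
   and simulated responders with controlled accuracy, so the whole pipeline
   is testable offline.

## The scoring rule

Let `g` be the gold diagnosis aligned to Mondo through exact-match
equivalence mappings, and `d` a predicted Mondo term. The prediction is
correct iff

    d = g   or   g ∈ desc_k(d)

where `desc_k(d)` is the set of terms reachable from `d` by at most `k`
is-a edges downward (`rollup_distance`, default k = 1). The second clause
is the subsumption **roll-up**: a general clinical diagnosis is credited
when the gold standard is one of its specific genetic subtypes. The rule is
directional — predicting the subtype when the gold is the grouping is *not*
credited (a `symmetric_rollup` flag enables the reverse for sensitivity
analysis). Top-k accuracy is the fraction of evaluable cases whose first
correct item has rank ≤ k; two methods are compared with McNemar's test on
the discordant Top-1 counts `b, c` (exact binomial when `b + c < 25`, else
χ² = (b−c)²/(b+c)).

## Worked example

The packaged toy ontology contains *geleophysic dysplasia*
(MONDO:0000127) with subtypes 1–3, where subtype 2 (MONDO:0013612) is
equivalent to OMIM:614185.

```python
from phenogauge import (
    GroundingConfig, DiseaseRef, ground_differential,
    read_ranked_response, score_case,
)
from phenogauge.fixtures import toy_disease_ontology, toy_disease_mappings

graph, mappings = toy_disease_ontology(), toy_disease_mappings()

response = """Here are the most likely diagnoses:

1. Marfan syndrome
2. geleophysic dysplasia
3. acromicric displasia
"""
diff = read_ranked_response(response, case_id="demo-1", method_id="llm")
items = ground_differential(diff, graph, GroundingConfig(threshold=0.8))
for rank, item in enumerate(items, 1):
    print(rank, item.raw_text, "->", item.mondo_id, item.match_kind, round(item.score, 3))

scored = score_case(items, DiseaseRef("OMIM:614185"), graph, mappings, rollup_distance=1)
print("rank_of_correct:", scored.rank_of_correct)
```

prints

```
1 Marfan syndrome -> MONDO:0099011 exact 1.0
2 geleophysic dysplasia -> MONDO:0000127 exact 1.0
3 acromicric displasia -> MONDO:0099010 similarity 0.95
rank_of_correct: 2
```

The misspelled "acromicric displasia" still grounds (similarity 0.95 ≥ the
0.8 threshold). The gold OMIM:614185 aligns to MONDO:0013612, which is one
is-a edge below the rank-2 prediction, so the case scores correct at rank 2
via roll-up; Marfan syndrome at rank 1 is wrong, so Top-1 misses and Top-3
hits.

## Command line

```bash
phenogauge simulate --out-dir bench/            # synthetic cohort + responses
phenogauge prompt  --cohort bench/phenopackets --out bench/prompts.jsonl
phenogauge ground  --responses bench/responses.jsonl \
                   --ontology bench/diseases.obograph.json --out bench/grounded.jsonl
phenogauge score   --grounded bench/grounded.jsonl --cohort bench/phenopackets \
                   --ontology bench/diseases.obograph.json \
                   --mappings bench/mappings.sssom.tsv --out bench/scored.jsonl
phenogauge metrics --scored bench/scored.jsonl --out bench/metrics.tsv
phenogauge compare --a bench/scored_A.jsonl --b bench/scored_B.jsonl
```

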