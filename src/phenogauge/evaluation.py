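"""Scoring differentials against gold diagnoses; Top-k metrics; paired tests.

The correctness rule is ontology-based. A predicted Mondo term is correct
for a case when (i) it equals the Mondo-aligned gold diagnosis (route
``exact_id``, or ``equivalence`` when the raw gold carried an OMIM/Orphanet
identifier resolved through the mapping table), or (ii) the gold diagnosis
is a close descendant of the prediction along is-a edges — the subsumption
roll-up, which credits a clinical grouping diagnosis (e.g. a genetically
heterogeneous syndrome) when the gold standard is one of its specific
genetic subtypes. "Close" is an edge-distance bound ``rollup_distance``
(default 1, the subtype-under-grouping case); the rule is directional by
default — a prediction more specific than the gold is not credited.

Per-cohort accuracy is summarised as Top-k: the proportion of evaluable
cases whose first correct item sits at rank ≤ k. Two methods are compared
case-paired with a McNemar test on Top-1 correctness: exact two-sided
binomial on the discordant counts when they are few (b + c < 25), the
chi-square approximation (b−c)²/(b+c), without continuity correction,
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .grounding import GroundedItem
from .ontology import MappingTable, OntologyGraph, align_to_mondo
from .pheno_io import CaseRecord, DiseaseRef

__all__ = [
    "ItemVerdict",
    "ScoredCase",
    "MetricsTable",
    "McNemarResult",
    "PairingError",
    "is_correct",
    "score_case",
    "topk_metrics",
    "metrics_frame",
    "mcnemar_top1",
    "stratify_by_organ",
    "stratify_by_term_count",
    "cohort_stats",
    "CohortStats",
    "DEFAULT_TERM_COUNT_BINS",
]

EXACT_BINOMIAL_MAX = 25  # below this many discordant pairs, use the exact test


class PairingError(ValueError):
    """Two scored sets do not cover the same cases."""


@dataclass(frozen=True)
class ItemVerdict:
    position: int  # 0-based original list position
    mondo_id: str | None
    correct: bool
    match_route: str  # exact_id | equivalence | rollup | none


@dataclass
class ScoredCase:
    """Per-case evaluation result for one method."""

    case_id: str
    method_id: str
    rank_of_correct: int | None
    item_verdicts: list[ItemVerdict] = field(default_factory=list)
    evaluable: bool = True


@dataclass
class MetricsTable:
    method_id: str
    stratum_id: str
    n_cases: int
    top_k: dict[int, float]


@dataclass
class McNemarResult:
    b: int  # method A correct at Top-1, B incorrect
    c: int  # method A incorrect, B correct
    statistic: float | None
    p_value: float
    variant: str  # exact_binomial | chi_square


# ---------------------------------------------------------------------------
# correctness rule


def is_correct(
    pred: str,
    gold: str,
    graph: OntologyGraph,
    rollup_distance: int | None = 1,
) -> tuple[bool, str]:
    """Judge one predicted Mondo term against the Mondo-aligned gold.

    Returns ``(True, "exact_id")`` on identity, ``(True, "rollup")`` when
    the gold is a descendant of the prediction within ``rollup_distance``
    is-a edges (``None`` = unbounded), and ``(False, "none")`` otherwise —
    including the reverse direction (specific prediction, general gold),
    which the default directional rule does not credit.
    """
    if pred not in graph:
        raise KeyError(pred)
    if gold not in graph:
        raise KeyError(gold)
    if pred == gold:
        return True, "exact_id"
    if gold in graph.descendants(pred, rollup_distance):
        return True, "rollup"
    return False, "none"


def score_case(
    grounded: Sequence[GroundedItem],
    gold_raw: DiseaseRef,
    graph: OntologyGraph,
    mappings: MappingTable,
    rollup_distance: int | None = 1,
    case_id: str = "",
    method_id: str = "",
    symmetric_rollup: bool = False,
) -> ScoredCase:
    """Score one grounded differential against a case's gold diagnosis.

    The gold is aligned to Mondo first; a case whose gold cannot be aligned
    (or is absent from the graph) is flagged unevaluable and excluded from
    metric denominators. Ranks are original list positions — ungrounded
    items stay in place and count as incorrect, and duplicate Mondo ids
    never shift ranks. ``symmetric_rollup`` additionally credits
    predictions that are close descendants of the gold (sensitivity
    analysis; off by default).
    """
    gold = align_to_mondo(gold_raw, mappings)
    if gold is None or gold not in graph:
        return ScoredCase(case_id, method_id, None, [], evaluable=False)
    gold_was_mapped = gold != gold_raw.id

    verdicts: list[ItemVerdict] = []
    rank: int | None = None
    for pos, item in enumerate(grounded):
        if item.mondo_id is None or item.mondo_id not in graph:
            verdicts.append(ItemVerdict(pos, None, False, "none"))
            continue
        ok, route = is_correct(item.mondo_id, gold, graph, rollup_distance)
        if not ok and symmetric_rollup:
            if item.mondo_id in graph.descendants(gold, rollup_distance):
                ok, route = True, "rollup"
        if ok and route == "exact_id" and gold_was_mapped:
            route = "equivalence"
        verdicts.append(ItemVerdict(pos, item.mondo_id, ok, route))
        if ok and rank is None:
            rank = pos + 1
    return ScoredCase(case_id, method_id, rank, verdicts)


# ---------------------------------------------------------------------------
# cohort metrics


def topk_metrics(
    scored: Sequence[ScoredCase],
    ks: Sequence[int] = (1, 3, 10),
    method_id: str | None = None,
    stratum_id: str = "all",
) -> MetricsTable:
    """Top-k proportions over the evaluable cases of one method.

    Each proportion is the fraction of evaluable cases whose
    ``rank_of_correct`` is ≤ k; by construction the proportions are
    non-decreasing in k.
    """
    if list(ks) != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    evaluable = [s for s in scored if s.evaluable]
    if not evaluable:
        raise ValueError("no evaluable cases — refusing a 0/0 proportion")
    if method_id is None:
        method_id = evaluable[0].method_id
    n = len(evaluable)
    top_k = {
        k: sum(
            1 for s in evaluable if s.rank_of_correct is not None and s.rank_of_correct <= k
        )
        / n
        for k in ks
    }
    return MetricsTable(method_id=method_id, stratum_id=stratum_id, n_cases=n, top_k=top_k)


def metrics_frame(tables: Iterable[MetricsTable]):
    """Flatten MetricsTables into the tabular artifact (one row per table)."""
    import pandas as pd

    rows = []
    for t in tables:
        row = {"method_id": t.method_id, "stratum_id": t.stratum_id, "n_cases": t.n_cases}
        row.update({f"top{k}": v for k, v in sorted(t.top_k.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def mcnemar_top1(
    scored_a: Sequence[ScoredCase], scored_b: Sequence[ScoredCase]
) -> McNemarResult:
    """Case-paired McNemar test on Top-1 correctness of two methods.

    Pairs by case_id over cases evaluable under both methods. With
    discordant counts b + c below 25 the exact two-sided binomial test is
    used; above, the chi-square statistic (b−c)²/(b+c) on 1 df without
    continuity correction. No discordant pairs at all gives p = 1 with an
    absent statistic.
    """
    a_by_case = {s.case_id: s for s in scored_a}
    b_by_case = {s.case_id: s for s in scored_b}
    if set(a_by_case) != set(b_by_case):
        diff = sorted(set(a_by_case) ^ set(b_by_case))
        raise PairingError(f"case sets differ; symmetric difference: {diff}")

    b = c = 0
    for case_id, sa in a_by_case.items():
        sb = b_by_case[case_id]
        if not (sa.evaluable and sb.evaluable):
            continue
        a_hit = sa.rank_of_correct == 1
        b_hit = sb.rank_of_correct == 1
        if a_hit and not b_hit:
            b += 1
        elif b_hit and not a_hit:
            c += 1

    n = b + c
    if n == 0:
        return McNemarResult(b, c, None, 1.0, "exact_binomial")
    if n < EXACT_BINOMIAL_MAX:
        p = stats.binomtest(b, n, 0.5, alternative="two-sided").pvalue
        return McNemarResult(b, c, None, float(p), "exact_binomial")
    statistic = (b - c) ** 2 / n
    p = stats.chi2.sf(statistic, df=1)
    return McNemarResult(b, c, float(statistic), float(p), "chi_square")


# ---------------------------------------------------------------------------
# stratification and cohort description


def stratify_by_organ(
    cohort: Iterable[CaseRecord],
    hpo_graph: OntologyGraph,
    root: str,
) -> list[CaseRecord]:
    """Cases with ≥1 *observed* feature that is ``root`` or a descendant.

    Excluded features never qualify: an excluded cardiovascular finding is
    evidence against cardiovascular involvement.
    """
    members = hpo_graph.descendants(root, None)
    return [
        case
        for case in cohort
        if any(f.term_id in members for f in case.observed())
    ]


DEFAULT_TERM_COUNT_BINS: tuple[tuple[int, int], ...] = (
    (0, 5),
    (6, 10),
    (11, 20),
    (21, 50),
)


def _bin_label(lo: int, hi: int) -> str:
    return f"<={hi}" if lo == 0 else f"{lo}-{hi}"


def stratify_by_term_count(
    cohort: Iterable[CaseRecord],
    bin_edges: Sequence[tuple[int, int]] = DEFAULT_TERM_COUNT_BINS,
) -> dict[str, list[CaseRecord]]:
    """Partition cases by their count of observed terms into inclusive bins.

    Bins must not overlap; cases covered by no bin land in an ``unbinned``
    bucket, never silently dropped.
    """
    bins = sorted(bin_edges)
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping bins: ({lo1},{hi1}) and ({lo2},{hi2})")
    out: dict[str, list[CaseRecord]] = {_bin_label(lo, hi): [] for lo, hi in bins}
    out["unbinned"] = []
    for case in cohort:
        n = len(case.observed())
        for lo, hi in bins:
            if lo <= n <= hi:
                out[_bin_label(lo, hi)].append(case)
                break
        else:
            out["unbinned"].append(case)
    return out


@dataclass
class CohortStats:
    n_cases: int
    n_unique_gold_diseases: int
    n_distinct_observed_hpo_terms: int
    mean_observed_terms_per_case: float
    n_distinct_source_publications: int | None


def cohort_stats(cohort: Sequence[CaseRecord]) -> CohortStats:
    """Descriptive statistics of a cohort (observed features only)."""
    if not cohort:
        raise ValueError("empty cohort")
    golds = {c.gold_diagnosis.id for c in cohort if c.gold_diagnosis}
    terms: set[str] = set()
    total = 0
    for c in cohort:
        obs = c.observed()
        total += len(obs)
        terms.update(f.term_id for f in obs)
    pubs = {c.source_publication for c in cohort if c.source_publication}
    return CohortStats(
        n_cases=len(cohort),
        n_unique_gold_diseases=len(golds),
        n_distinct_observed_hpo_terms=len(terms),
        mean_observed_terms_per_case=total / len(cohort),
        n_distinct_source_publications=len(pubs) if pubs else None,
    )
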