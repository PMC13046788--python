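"""Roll-up scoring, Top-k metrics, stratification, and paired tests."""

import itertools
import math

import numpy as np
import pytest

from phenogauge.evaluation import (
    DEFAULT_TERM_COUNT_BINS,
    PairingError,
    ScoredCase,
    cohort_stats,
    is_correct,
    mcnemar_top1,
    metrics_frame,
    score_case,
    stratify_by_organ,
    stratify_by_term_count,
    topk_metrics,
)
from phenogauge.grounding import GroundedItem
from phenogauge.ontology import MappingTable, OntologyGraph, Term
from phenogauge.pheno_io import CaseRecord, DiseaseRef, PhenotypeFeature

GD, GD2 = "MONDO:0000127", "MONDO:0013612"


def grounded(*mondo_ids):
    return [
        GroundedItem(f"item {i}", mid, "exact" if mid else "none", 1.0 if mid else 0.0)
        for i, mid in enumerate(mondo_ids)
    ]


class TestIsCorrect:
    def test_general_prediction_credits_specific_gold(self, toy_graph):
        assert is_correct(GD, GD2, toy_graph, 1) == (True, "rollup")

    def test_identity_is_exact(self, toy_graph):
        assert is_correct(GD2, GD2, toy_graph, 1) == (True, "exact_id")

    def test_reverse_direction_not_credited(self, toy_graph):
        assert is_correct(GD2, GD, toy_graph, 1) == (False, "none")

    def test_rollup_respects_distance_bound(self, toy_graph):
        grouping = "MONDO:0099020"  # two is-a edges above the subtype
        assert is_correct(grouping, GD2, toy_graph, 1) == (False, "none")
        assert is_correct(grouping, GD2, toy_graph, 2) == (True, "rollup")
        assert is_correct(grouping, GD2, toy_graph, None) == (True, "rollup")

    def test_unknown_curie_raises(self, toy_graph):
        with pytest.raises(KeyError):
            is_correct("MONDO:4444444", GD2, toy_graph, 1)


class TestScoreCase:
    def test_worked_example_rank_two(self, toy_graph, toy_mappings):
        """Hand-trace: items [distractor, grouping term, distractor] against
        an OMIM gold that aligns to the grouping's subtype -> rank 2 via
        equivalence alignment plus roll-up at distance 1."""
        items = grounded("MONDO:0099011", GD, "MONDO:0099010")
        scored = score_case(items, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1)
        assert scored.rank_of_correct == 2
        assert scored.item_verdicts[1].match_route == "rollup"
        assert not scored.item_verdicts[0].correct

    def test_equivalence_route_recorded_for_mapped_gold(self, toy_graph, toy_mappings):
        scored = score_case(
            grounded(GD2), DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1
        )
        assert scored.rank_of_correct == 1
        assert scored.item_verdicts[0].match_route == "equivalence"

    def test_exact_id_route_for_mondo_gold(self, toy_graph, toy_mappings):
        scored = score_case(
            grounded(GD2), DiseaseRef(GD2), toy_graph, toy_mappings, 1
        )
        assert scored.item_verdicts[0].match_route == "exact_id"

    def test_no_correct_item_gives_none(self, toy_graph, toy_mappings):
        items = grounded(*(["MONDO:0099011"] * 10))
        scored = score_case(items, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1)
        assert scored.rank_of_correct is None

    def test_empty_differential(self, toy_graph, toy_mappings):
        scored = score_case([], DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1)
        assert scored.rank_of_correct is None
        assert scored.item_verdicts == []
        assert scored.evaluable

    def test_ungrounded_items_hold_their_rank_slot(self, toy_graph, toy_mappings):
        items = grounded(None, GD2)
        scored = score_case(items, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1)
        assert scored.rank_of_correct == 2
        assert scored.item_verdicts[0].match_route == "none"

    def test_unalignable_gold_flagged_unevaluable(self, toy_graph):
        scored = score_case(
            grounded(GD2), DiseaseRef("OMIM:999999"), toy_graph, MappingTable(), 1
        )
        assert not scored.evaluable
        assert scored.rank_of_correct is None

    def test_duplicates_do_not_shift_ranks(self, toy_graph, toy_mappings):
        items = grounded("MONDO:0099011", "MONDO:0099011", GD2)
        scored = score_case(items, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1)
        assert scored.rank_of_correct == 3

    def test_rank_stable_under_permutation_after_first_hit(self, toy_graph, toy_mappings):
        tail = ["MONDO:0099010", "MONDO:0099011", "MONDO:0099012"]
        ranks = set()
        for perm in itertools.permutations(tail):
            items = grounded("MONDO:0099013", GD2, *perm)
            scored = score_case(
                items, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings, 1
            )
            ranks.add(scored.rank_of_correct)
        assert ranks == {2}

    def test_symmetric_rollup_flag_credits_reverse_direction(
        self, toy_graph, toy_mappings
    ):
        items = grounded(GD2)  # specific prediction, general gold
        strict = score_case(items, DiseaseRef(GD), toy_graph, toy_mappings, 1)
        loose = score_case(
            items, DiseaseRef(GD), toy_graph, toy_mappings, 1, symmetric_rollup=True
        )
        assert strict.rank_of_correct is None
        assert loose.rank_of_correct == 1

    def test_enlarging_rollup_distance_never_decreases_topk(
        self, toy_graph, toy_mappings
    ):
        differentials = [
            grounded("MONDO:0099020", "MONDO:0099011"),
            grounded(GD, "MONDO:0099010"),
            grounded("MONDO:0099011", "MONDO:0099012"),
        ]
        prev = -1.0
        for distance in (0, 1, 2, None):
            scored = [
                score_case(d, DiseaseRef("OMIM:614185"), toy_graph, toy_mappings,
                           distance, case_id=str(i))
                for i, d in enumerate(differentials)
            ]
            p10 = topk_metrics(scored, [10]).top_k[10]
            assert p10 >= prev
            prev = p10


class TestTopkMetrics:
    def scored_from_ranks(self, ranks):
        return [
            ScoredCase(f"c{i}", "m", rank) for i, rank in enumerate(ranks)
        ]

    def test_hand_count(self):
        # ranks [1, 4, None, 2]: one case at rank 1; ranks 1 and 2 within 3;
        # ranks 1, 2 and 4 within 10
        table = topk_metrics(self.scored_from_ranks([1, 4, None, 2]), [1, 3, 10])
        assert table.top_k == {1: 0.25, 3: 0.50, 10: 0.75}
        assert table.n_cases == 4

    def test_all_rank_one(self):
        table = topk_metrics(self.scored_from_ranks([1, 1, 1]), [1, 3, 10])
        assert table.top_k == {1: 1.0, 3: 1.0, 10: 1.0}

    def test_all_missing(self):
        table = topk_metrics(self.scored_from_ranks([None, None]), [1, 3, 10])
        assert table.top_k == {1: 0.0, 3: 0.0, 10: 0.0}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            topk_metrics([], [1, 3, 10])
        with pytest.raises(ValueError):
            topk_metrics([ScoredCase("c", "m", None, evaluable=False)], [1])

    def test_unsorted_ks_rejected(self):
        with pytest.raises(ValueError):
            topk_metrics(self.scored_from_ranks([1]), [3, 1])

    def test_metrics_frame_columns(self):
        df = metrics_frame([topk_metrics(self.scored_from_ranks([1, None]), [1, 3, 10])])
        assert list(df.columns) == [
            "method_id", "stratum_id", "n_cases", "top1", "top3", "top10",
        ]


def paired_scored(b, c, n_concordant=3):
    """Two scored sets with exactly b and c discordant Top-1 pairs."""
    a_list, b_list = [], []
    i = 0
    for _ in range(b):
        a_list.append(ScoredCase(f"c{i}", "A", 1))
        b_list.append(ScoredCase(f"c{i}", "B", None))
        i += 1
    for _ in range(c):
        a_list.append(ScoredCase(f"c{i}", "A", 5))
        b_list.append(ScoredCase(f"c{i}", "B", 1))
        i += 1
    for _ in range(n_concordant):
        a_list.append(ScoredCase(f"c{i}", "A", 1))
        b_list.append(ScoredCase(f"c{i}", "B", 1))
        i += 1
    return a_list, b_list


def brute_force_exact_p(b, c):
    """Enumerate all 2^(b+c) equally likely discordant assignments and count
    those at least as extreme (two-sided) as the observed split."""
    n = b + c
    observed = abs(b - n / 2)
    hits = 0
    for bits in itertools.product([0, 1], repeat=n):
        x = sum(bits)
        if abs(x - n / 2) >= observed - 1e-12:
            hits += 1
    return hits / 2 ** n


class TestMcNemar:
    def test_exact_p_for_one_sided_discordance(self):
        result = mcnemar_top1(*paired_scored(10, 0))
        assert result.variant == "exact_binomial"
        assert result.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_symmetric_discordance_p_is_one(self):
        assert mcnemar_top1(*paired_scored(5, 5)).p_value == pytest.approx(1.0)

    def test_chi_square_closed_form(self):
        result = mcnemar_top1(*paired_scored(30, 10))
        assert result.variant == "chi_square"
        assert result.statistic == pytest.approx((30 - 10) ** 2 / 40)
        assert result.p_value == pytest.approx(
            math.erfc(math.sqrt(10.0 / 2)), rel=1e-6
        )

    def test_no_discordance_gives_p_one_without_statistic(self):
        result = mcnemar_top1(*paired_scored(0, 0))
        assert result.p_value == 1.0
        assert result.statistic is None

    @pytest.mark.parametrize(
        "b,c", [(0, 1), (1, 1), (2, 5), (3, 3), (4, 8), (0, 12), (6, 6), (7, 2)]
    )
    def test_exact_branch_matches_brute_force_oracle(self, b, c):
        result = mcnemar_top1(*paired_scored(b, c))
        assert result.variant == "exact_binomial"
        assert result.p_value == pytest.approx(brute_force_exact_p(b, c))

    @pytest.mark.parametrize("b,c,exact", [(5, 3, True), (40, 22, False)])
    def test_matches_statsmodels_cross_check(self, b, c, exact):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        result = mcnemar_top1(*paired_scored(b, c))
        table = [[7, b], [c, 9]]
        sm = sm_mcnemar(table, exact=exact, correction=False)
        assert result.p_value == pytest.approx(float(sm.pvalue), rel=1e-9)

    def test_mismatched_case_sets_listed(self):
        a_list, b_list = paired_scored(1, 1)
        with pytest.raises(PairingError, match="c0"):
            mcnemar_top1(a_list[1:], b_list)

    def test_unevaluable_pairs_excluded(self):
        a_list, b_list = paired_scored(10, 0)
        a_list[0] = ScoredCase("c0", "A", 1, evaluable=False)
        result = mcnemar_top1(a_list, b_list)
        assert result.b == 9


def make_case(case_id, observed_terms, excluded_terms=(), gold="OMIM:614185",
              pub=None):
    features = [PhenotypeFeature(t, f"label {t}") for t in observed_terms]
    features += [
        PhenotypeFeature(t, f"label {t}", excluded=True) for t in excluded_terms
    ]
    return CaseRecord(
        case_id=case_id,
        features=features,
        gold_diagnosis=DiseaseRef(gold),
        source_publication=pub,
    )


@pytest.fixture(scope="module")
def hpo_toy():
    nodes = {
        "HP:0000001": Term("All"),
        "HP:0001626": Term("Abnormality of the cardiovascular system"),
        "HP:0001627": Term("Abnormal heart morphology"),
        "HP:0000707": Term("Abnormality of the nervous system"),
        "HP:0001250": Term("Seizure"),
    }
    edges = [
        ("HP:0001626", "HP:0000001"),
        ("HP:0000707", "HP:0000001"),
        ("HP:0001627", "HP:0001626"),
        ("HP:0001250", "HP:0000707"),
    ]
    return OntologyGraph(nodes, edges)


class TestStratification:
    def test_organ_subset_by_descendant_terms(self, hpo_toy):
        cohort = [
            make_case("c1", ["HP:0001627"]),          # cardiovascular descendant
            make_case("c2", ["HP:0001626"]),          # the root itself
            make_case("c3", ["HP:0001250"]),          # nervous only
            make_case("c4", ["HP:0001250", "HP:0001627"]),
            make_case("c5", []),
        ]
        subset = stratify_by_organ(cohort, hpo_toy, "HP:0001626")
        assert [c.case_id for c in subset] == ["c1", "c2", "c4"]

    def test_root_without_annotations_gives_empty_subset(self, hpo_toy):
        cohort = [make_case("c1", ["HP:0001250"])]
        assert stratify_by_organ(cohort, hpo_toy, "HP:0001626") == []

    def test_excluded_features_never_qualify(self, hpo_toy):
        cohort = [make_case("c1", ["HP:0001250"], excluded_terms=["HP:0001627"])]
        assert stratify_by_organ(cohort, hpo_toy, "HP:0001626") == []

    def test_unknown_root_raises(self, hpo_toy):
        with pytest.raises(KeyError):
            stratify_by_organ([], hpo_toy, "HP:7777777")

    def test_term_count_bins(self):
        terms = [f"HP:{i:07d}" for i in range(60)]
        cohort = [
            make_case("c7", terms[:7]),
            make_case("c0", []),
            make_case("c60", terms[:60]),
            make_case("c5", terms[:5]),
            make_case("c21", terms[:21]),
        ]
        binned = stratify_by_term_count(cohort, DEFAULT_TERM_COUNT_BINS)
        assert [c.case_id for c in binned["6-10"]] == ["c7"]
        assert {c.case_id for c in binned["<=5"]} == {"c0", "c5"}
        assert [c.case_id for c in binned["21-50"]] == ["c21"]
        assert [c.case_id for c in binned["unbinned"]] == ["c60"]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            stratify_by_term_count([], [(0, 5), (5, 10)])


class TestCohortStats:
    def test_hand_counts(self):
        cohort = [
            make_case("c1", ["HP:0000001", "HP:0000002"], gold="OMIM:1", pub="PMID:1"),
            make_case("c2", ["HP:0000002", "HP:0000003"], gold="OMIM:1", pub="PMID:2"),
            make_case("c3", ["HP:0000003"], gold="OMIM:2", pub="PMID:1"),
        ]
        stats = cohort_stats(cohort)
        assert stats.n_cases == 3
        assert stats.n_unique_gold_diseases == 2
        assert stats.n_distinct_observed_hpo_terms == 3
        assert stats.mean_observed_terms_per_case == pytest.approx(5 / 3)
        assert stats.n_distinct_source_publications == 2

    def test_single_case(self):
        stats = cohort_stats([make_case("c1", ["HP:0000001"])])
        assert stats.n_cases == 1
        assert stats.mean_observed_terms_per_case == 1.0
        assert stats.n_unique_gold_diseases == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_stats([])


def test_topk_parameter_recovery_direct_ranks():
    """A responder with true Top-1 probability 0.30 over 5000 cases is
    recovered within sampling error when scoring ranks directly."""
    rng = np.random.default_rng(123)
    ranks = [1 if rng.random() < 0.30 else None for _ in range(5000)]
    scored = [ScoredCase(f"c{i}", "m", r) for i, r in enumerate(ranks)]
    p1 = topk_metrics(scored, [1]).top_k[1]
    assert abs(p1 - 0.30) < 0.02
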