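"""Leave-one-out discordance screening: reference flags, oracle equivalence,
order invariance and monotonicity."""

import numpy as np
import pytest

from panelval import (
    DeviancePolicy,
    LikertScale,
    RatingMatrix,
    assemble_final_panel,
    flag_deviant_answers,
    loo_mean,
    original_pool,
    screen_experts,
)

from conftest import random_matrix


def brute_force_flags(matrix, pool, d=3.0, m=2):
    """First-principles recomputation: plain Python sums, no shared code path."""
    flags = set()
    for e in pool:
        for item in matrix.item_ids:
            others = [matrix.rating(o, item) for o in pool if o != e]
            mean = sum(others) / len(others)
            if abs(matrix.rating(e, item) - mean) >= d:
                flags.add((e, item))
    excluded = [
        e for e in pool if sum(1 for (fe, _) in flags if fe == e) >= m
    ]
    return flags, excluded


class TestLooMean:
    def test_physician_example(self, physicians):
        matrix, profiles = physicians
        pool = original_pool(matrix, profiles)
        assert loo_mean(matrix, "3", "12", pool) == pytest.approx(38 / 9)

    def test_nurse_example(self, nurses):
        matrix, profiles = nurses
        pool = original_pool(matrix, profiles)
        assert loo_mean(matrix, "7", "2", pool) == pytest.approx(37 / 9)

    def test_unanimous_other_experts(self):
        m = RatingMatrix("p", LikertScale(1, 5), ["a", "b", "c"], ["Q"], [[1], [5], [5]])
        assert loo_mean(m, "a", "Q", ["a", "b", "c"]) == 5.0

    def test_expert_must_be_in_pool(self, physicians):
        matrix, _ = physicians
        with pytest.raises(ValueError, match="not in pool"):
            loo_mean(matrix, "11", "1", ["1", "2", "3"])


class TestReferenceFlags:
    def test_physician_flags_are_the_marked_cells(self, physicians):
        matrix, profiles = physicians
        flags = flag_deviant_answers(matrix, original_pool(matrix, profiles))
        assert {(f.expert_id, f.item_id) for f in flags} == {
            ("3", "12"), ("3", "15"), ("3", "27"), ("3", "28")
        }

    def test_nurse_deviant_expert_flagged_at_marked_cells(self, nurses):
        matrix, profiles = nurses
        flags = flag_deviant_answers(matrix, original_pool(matrix, profiles))
        by_expert = {}
        for f in flags:
            by_expert.setdefault(f.expert_id, set()).add(f.item_id)
        assert by_expert["7"] == {"2", "5"}
        # single-flag experts: a difference of exactly 3.0 flags (inclusive rule)
        assert by_expert.get("1") == {"19"}
        assert by_expert.get("8") == {"27"}

    def test_constant_matrix_has_no_flags(self):
        m = RatingMatrix("c", LikertScale(1, 5), list("abcd"), ["Q1", "Q2"], np.full((4, 2), 4))
        assert flag_deviant_answers(m, list("abcd")) == []

    def test_sd_multiple_mode_contradicts_marked_cells(self, physicians):
        """The SD-multiple reading of the rule is kept as an option but does
        not reproduce the published flags (negative control)."""
        matrix, profiles = physicians
        pool = original_pool(matrix, profiles)
        flags = flag_deviant_answers(matrix, pool, DeviancePolicy(mode="sd_multiple"))
        flagged = {(f.expert_id, f.item_id) for f in flags}
        assert flagged != {("3", "12"), ("3", "15"), ("3", "27"), ("3", "28")}
        assert len(screen_experts(matrix, pool, DeviancePolicy(mode="sd_multiple")).excluded_experts) > 1


class TestScreenExperts:
    def test_physician_exclusion(self, physicians):
        matrix, profiles = physicians
        result = screen_experts(matrix, original_pool(matrix, profiles))
        assert result.excluded_experts == ("3",)
        assert result.flag_count_per_expert["3"] == 4

    def test_nurse_exclusion_retains_single_flag_experts(self, nurses):
        matrix, profiles = nurses
        result = screen_experts(matrix, original_pool(matrix, profiles))
        assert result.excluded_experts == ("7",)
        assert "8" in result.retained_expert_ids
        assert "1" in result.retained_expert_ids

    def test_min_flags_one_excludes_superset(self, nurses):
        matrix, profiles = nurses
        pool = original_pool(matrix, profiles)
        strict = screen_experts(matrix, pool, DeviancePolicy(min_flagged_items=1))
        assert set(strict.excluded_experts) >= {"7"}
        _, brute = brute_force_flags(matrix, pool, m=1)
        assert set(strict.excluded_experts) == set(brute)


class TestAssembleFinalPanel:
    def test_physician_final_panel(self, physicians):
        matrix, profiles = physicians
        result = screen_experts(matrix, original_pool(matrix, profiles))
        final = assemble_final_panel(matrix, result, ["11"])
        assert final.n_experts == 10
        assert final.expert_ids[-1] == "11"
        assert "3" not in final.expert_ids

    def test_nurse_final_panel_expert_set(self, nurses):
        matrix, profiles = nurses
        result = screen_experts(matrix, original_pool(matrix, profiles))
        final = assemble_final_panel(matrix, result, ["11"])
        assert sorted(final.expert_ids, key=int) == ["1", "2", "3", "4", "5", "6", "8", "9", "10", "11"]

    def test_empty_replacement_list(self, physicians):
        matrix, profiles = physicians
        result = screen_experts(matrix, original_pool(matrix, profiles))
        final = assemble_final_panel(matrix, result)
        assert final.expert_ids == result.retained_expert_ids

    def test_replacement_overlap_rejected(self, physicians):
        matrix, profiles = physicians
        result = screen_experts(matrix, original_pool(matrix, profiles))
        with pytest.raises(ValueError, match="already in screened pool"):
            assemble_final_panel(matrix, result, ["1"])


class TestInvariantsAndOracle:
    def test_flags_invariant_under_item_and_pool_permutation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = random_matrix(rng, n_experts=6, n_items=5)
            pool = list(m.expert_ids)
            base = {(f.expert_id, f.item_id) for f in flag_deviant_answers(m, pool)}
            # permute item columns
            perm = rng.permutation(m.n_items)
            m2 = RatingMatrix(
                m.panel_id, m.scale, m.expert_ids,
                [m.item_ids[i] for i in perm], m.ratings[:, perm],
            )
            assert {(f.expert_id, f.item_id) for f in flag_deviant_answers(m2, pool)} == base
            # permute the order the pool is passed in
            shuffled = list(pool)
            rng.shuffle(shuffled)
            assert {(f.expert_id, f.item_id) for f in flag_deviant_answers(m, shuffled)} == base

    def test_matches_brute_force_on_small_panels(self):
        rng = np.random.default_rng(5)
        scale = LikertScale(1, 3)
        for _ in range(200):
            m = random_matrix(rng, n_experts=int(rng.integers(2, 6)),
                              n_items=int(rng.integers(1, 6)), scale=scale)
            pool = list(m.expert_ids)
            expected_flags, expected_excluded = brute_force_flags(m, pool)
            result = screen_experts(m, pool)
            assert {(f.expert_id, f.item_id) for f in result.flags} == expected_flags
            assert set(result.excluded_experts) == set(expected_excluded)

    def test_raising_threshold_or_min_flags_never_enlarges_exclusions(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            m = random_matrix(rng, n_experts=6, n_items=8)
            pool = list(m.expert_ids)
            for d_lo, d_hi in [(1.0, 2.0), (2.0, 3.0)]:
                lo = set(screen_experts(m, pool, DeviancePolicy(deviance_threshold=d_lo)).excluded_experts)
                hi = set(screen_experts(m, pool, DeviancePolicy(deviance_threshold=d_hi)).excluded_experts)
                assert hi <= lo
            for m_lo, m_hi in [(1, 2), (2, 3)]:
                lo = set(screen_experts(m, pool, DeviancePolicy(deviance_threshold=2.0, min_flagged_items=m_lo)).excluded_experts)
                hi = set(screen_experts(m, pool, DeviancePolicy(deviance_threshold=2.0, min_flagged_items=m_hi)).excluded_experts)
                assert hi <= lo
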