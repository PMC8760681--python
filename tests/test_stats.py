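"""Statistical battery: hand-computed values and algebraic identities."""

import numpy as np
import pandas as pd
import pytest

from optolfp.io_core import ValidationError
from optolfp.stats_report import (average_replicates, one_sample_t, paired_t,
                                  pearson_r, posthoc, rank_tests, rm_anova,
                                  two_way_rm_anova)


class TestOneSampleT:
    def test_hand_computed_statistic(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu=0.0)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-3)

    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t([-1.0, 0.0, 1.0], mu=0.0)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_bonferroni_alpha_recorded(self):
        res = one_sample_t([1.0, 2.0, 3.0], n_comparisons=2)
        assert res.alpha == 0.025

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValidationError):
            one_sample_t([2.0, 2.0, 2.0])


class TestPairedT:
    def test_reduces_to_one_sample_on_differences(self):
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)

    def test_swapping_flips_sign(self):
        a, b = [2.0, 4.0, 7.0], [1.0, 2.0, 3.0]
        assert paired_t(a, b).statistic == pytest.approx(
            -paired_t(b, a).statistic)

    def test_identical_pairs_error(self):
        with pytest.raises(ValidationError):
            paired_t([1.0, 2.0], [1.0, 2.0])


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self):
        data = np.tile([[1.0], [2.0], [3.0]], (1, 3))
        assert rm_anova(data).statistic == 0.0

    def test_two_conditions_equal_paired_t_squared(self, rng):
        data = rng.normal(size=(8, 2))
        F = rm_anova(data).statistic
        t = paired_t(data[:, 0], data[:, 1]).statistic
        assert F == pytest.approx(t ** 2, rel=1e-9)

    def test_subject_offsets_removed(self, rng):
        data = rng.normal(size=(6, 3))
        shifted = data.copy()
        shifted[2] += 100.0
        assert rm_anova(shifted).statistic == pytest.approx(
            rm_anova(data).statistic, rel=1e-9)

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            rm_anova(data)

    def test_two_way_reports_main_effects_and_interaction(self, rng):
        rows = [dict(subj=s, band=b, hour=h, y=rng.normal())
                for s in range(5) for b in ("theta", "gamma")
                for h in (1, 2, 3)]
        out = two_way_rm_anova(pd.DataFrame(rows), "y", ["band", "hour"],
                               "subj")
        assert set(out) == {"band", "hour", "band * hour"}


class TestPosthoc:
    def test_identical_groups_all_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        for method in ("tukey", "dunnett"):
            rows = posthoc([g, g, g], method)
            assert all(r["p_adjusted"] > 0.99 for r in rows)

    def test_dunn_adjusted_at_least_unadjusted(self, rng):
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.5, 2.0)]
        rows = posthoc(groups, "dunn")
        assert all(r["p_adjusted"] >= r["p_unadjusted"] - 1e-12 for r in rows)

    def test_dunn_largest_gap_smallest_p(self):
        rows = posthoc([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], "dunn")
        by_pair = {r["pair"]: r["p_adjusted"] for r in rows}
        assert by_pair[(0, 2)] <= by_pair[(0, 1)]
        assert by_pair[(0, 2)] <= by_pair[(1, 2)]

    def test_dunnett_compares_against_control_only(self, rng):
        rows = posthoc([rng.normal(size=5) for _ in range(4)], "dunnett",
                       control=0)
        assert sorted(r["pair"] for r in rows) == [(0, 1), (0, 2), (0, 3)]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            posthoc([[1.0, 2.0]], "scheffe")


class TestRankTests:
    def test_friedman_perfect_ordering(self):
        """3 subjects x 3 conditions, every row strictly increasing: Fr = 6."""
        res = rank_tests([[1, 2, 3], [4, 5, 6], [7, 8, 9]], "friedman")
        assert res.statistic == pytest.approx(6.0)

    def test_kruskal_worked_example(self):
        res = rank_tests([[1, 2], [3, 4], [5, 6]], "kruskal")
        assert res.statistic == pytest.approx(4.571, abs=1e-3)

    def test_friedman_needs_three_conditions(self):
        with pytest.raises(ValidationError):
            rank_tests([[1, 2], [3, 4]], "friedman")


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = pearson_r([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0])
        assert res.statistic == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAverageReplicates:
    def test_two_sessions_mean(self):
        df = pd.DataFrame({"animal": [0, 0], "session_type": ["ref", "ref"],
                           "value": [10.0, 12.0]})
        out = average_replicates(df, ["animal", "session_type"])
        assert out["value"].tolist() == [11.0]

    def test_single_session_passthrough_and_three_way_mean(self):
        df = pd.DataFrame({"animal": [0, 1, 1, 1],
                           "session_type": ["ref"] * 4,
                           "value": [5.0, 1.0, 2.0, 6.0]})
        out = average_replicates(df, ["animal", "session_type"])
        assert out[out["animal"] == 0]["value"].item() == 5.0
        assert out[out["animal"] == 1]["value"].item() == 3.0
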