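"""Statistical battery: hand-computed oracles and structural properties."""

import numpy as np
import pytest
from scipy import special

from neuroacw.simulate import make_region_table
from neuroacw.stats import (
    bh_fdr,
    cohens_d,
    one_way_anova,
    regress_out_axis,
    ttest_core_periphery,
    tukey_posthoc,
    two_way_anova,
)


class TestTTest:
    def test_hand_computed_example(self):
        # pooled SD = 1, mean difference -2 => d = -2; t = d*sqrt(n1*n2/(n1+n2))
        report = ttest_core_periphery(
            [1, 2, 3, 3, 4, 5], ["periphery"] * 3 + ["core"] * 3
        )
        assert report.t == pytest.approx(-2.449, abs=1e-3)
        assert report.cohens_d == pytest.approx(-2.0)
        assert report.df == 4

    def test_identical_groups_give_zero(self):
        report = ttest_core_periphery(
            [1, 2, 3, 1, 2, 3], ["periphery"] * 3 + ["core"] * 3
        )
        assert report.t == 0.0
        assert report.cohens_d == 0.0

    def test_sign_follows_periphery_minus_core(self):
        report = ttest_core_periphery(
            [10, 11, 12, 1, 2, 3], ["periphery"] * 3 + ["core"] * 3
        )
        assert report.t > 0 and report.cohens_d > 0
        assert np.sign(report.t) == np.sign(report.mean1 - report.mean2)

    def test_empty_group_raises_with_division_name(self):
        with pytest.raises(ValueError, match="RCP"):
            ttest_core_periphery([1, 2, 3], ["periphery"] * 3, division_name="RCP")

    def test_excluded_labels_are_callers_responsibility(self):
        # excluded regions must be dropped before calling; they are not a group
        with pytest.raises(ValueError):
            ttest_core_periphery([1, 2], ["excluded", "excluded"])


class TestAnova:
    def test_one_way_structural_df_schaefer(self):
        table = make_region_table("schaefer", 0)
        values = np.random.default_rng(0).normal(size=200)
        effect = one_way_anova(values, table["network"])["group"]
        assert (effect.df_effect, effect.df_error) == (6, 193)

    def test_one_way_structural_df_ji(self):
        table = make_region_table("ji", 0)
        values = np.random.default_rng(0).normal(size=360)
        effect = one_way_anova(values, table["network"])["group"]
        assert (effect.df_effect, effect.df_error) == (11, 348)

    def test_equal_group_means_give_zero_f(self):
        effect = one_way_anova([1, 2, 1, 2, 1, 2], list("aabbcc"))["group"]
        assert effect.F == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "a"])

    def test_two_way_structural_df(self):
        rng = np.random.default_rng(1)
        for n_regions, expect in ((200, 594), (360, 1074)):
            values = rng.normal(size=n_regions * 3)
            tasks = np.repeat(["StoryM", "Motort", "Wrkmem"], n_regions)
            cp = np.tile(
                np.r_[["periphery"] * (n_regions // 2), ["core"] * (n_regions - n_regions // 2)],
                3,
            )
            report = two_way_anova(values, tasks, cp)
            assert report["cp"].df_error == expect
            assert report["cp"].df_effect == 1
            assert report["task"].df_effect == 2

    def test_injected_cp_effect_dominates_eta_squared(self):
        rng = np.random.default_rng(2)
        n = 300
        cp = np.tile(np.r_[["periphery"] * 150, ["core"] * 150], 3)
        tasks = np.repeat(["StoryM", "Motort", "Wrkmem"], n)
        values = rng.normal(size=3 * n) + np.where(cp == "core", 2.0, 0.0)
        report = two_way_anova(values, tasks, cp)
        assert report["cp"].eta_sq > 0.3
        assert report["task"].eta_sq < 0.02
        assert report["cp"].p < 1e-10

    def test_eta_squared_decomposition_sums_to_one(self):
        rng = np.random.default_rng(3)
        report = two_way_anova(
            rng.normal(size=120),
            np.repeat(["a", "b", "c"], 40),
            np.tile(np.r_[["periphery"] * 20, ["core"] * 20], 3),
        )
        assert sum(e.eta_sq for e in report.effects) == pytest.approx(1.0)
        assert all(0 <= e.eta_sq <= 1 for e in report.effects)

    def test_two_way_collapses_to_one_way_in_balanced_design(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=120)
        tasks = np.repeat(["a", "b", "c"], 40)
        cp = np.tile(np.r_[["periphery"] * 20, ["core"] * 20], 3)
        # balanced orthogonal design: the task sum of squares (hence its
        # share of the total) is identical whether or not CP is modelled
        full = two_way_anova(values, tasks, cp)
        one = one_way_anova(values, tasks)["group"]
        assert full["task"].eta_sq == pytest.approx(one.eta_sq, rel=1e-10)
        assert full["task"].F == pytest.approx(one.F, rel=0.2)

    def test_empty_cell_identified(self):
        with pytest.raises(ValueError, match="StoryM.*core"):
            two_way_anova(
                [1, 2, 3, 4],
                ["StoryM", "StoryM", "Motort", "Motort"],
                ["periphery", "periphery", "periphery", "core"],
            )

    def test_f_and_p_consistent_via_beta_incomplete(self):
        # independent CDF route: F sf via the regularized incomplete beta
        table = make_region_table("schaefer", 0)
        values = np.random.default_rng(5).normal(size=200)
        effect = one_way_anova(values, table["network"])["group"]
        d1, d2 = effect.df_effect, effect.df_error
        x = d2 / (d2 + d1 * effect.F)
        assert effect.p == pytest.approx(float(special.betainc(d2 / 2, d1 / 2, x)), rel=1e-10)


class TestTukey:
    @staticmethod
    def design(rng, shift_by_task=None, n=50):
        shift_by_task = shift_by_task or {}
        values, tasks, cp = [], [], []
        for task in ("StoryM", "Motort", "Wrkmem"):
            for group in ("periphery", "core"):
                shift = shift_by_task.get((task, group), 0.0)
                values.append(rng.normal(shift, 1.0, n))
                tasks += [task] * n
                cp += [group] * n
        return np.concatenate(values), np.array(tasks), np.array(cp)

    def test_null_cells_give_large_adjusted_p(self):
        values, tasks, cp = self.design(np.random.default_rng(0))
        report = tukey_posthoc(values, tasks, cp)
        assert all(c.p_adj > 0.5 for c in report.contrasts)

    def test_single_task_gap_detected_only_there(self):
        values, tasks, cp = self.design(
            np.random.default_rng(1), {("StoryM", "core"): 1.5}
        )
        report = tukey_posthoc(values, tasks, cp)
        by_task = {c.task: c for c in report.contrasts}
        assert by_task["StoryM"].p_adj < 0.001
        assert by_task["Motort"].p_adj > 0.05
        assert by_task["Wrkmem"].p_adj > 0.05

    def test_contrast_sign_is_periphery_minus_core(self):
        values, tasks, cp = self.design(
            np.random.default_rng(2), {("StoryM", "core"): 2.0}
        )
        report = tukey_posthoc(values, tasks, cp)
        storym = next(c for c in report.contrasts if c.task == "StoryM")
        assert storym.t < 0 and storym.cohens_d < 0


class TestFdrAndAxis:
    def test_step_up_worked_example(self):
        # thresholds 0.0125 / 0.025 / 0.0375 / 0.05: largest k with
        # p_(k) <= k/m * alpha is k = 3
        reject, p_adj = bh_fdr([0.001, 0.02, 0.03, 0.5], alpha=0.05)
        assert reject.sum() == 3
        assert not reject[3]

    def test_all_ones_and_all_zeros(self):
        assert bh_fdr([1.0, 1.0, 1.0])[0].sum() == 0
        assert bh_fdr([0.0, 0.0, 0.0])[0].all()

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        _, p_adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.4])

    def test_linear_trend_removed_exactly(self):
        y = np.linspace(-70, 30, 50)
        values = 3.0 * y + 7.0
        residuals = regress_out_axis(values, y)
        assert np.max(np.abs(residuals)) < 1e-9

    def test_residuals_orthogonal_to_axis(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=80)
        values = rng.normal(size=80)
        residuals = regress_out_axis(values, y)
        assert abs(residuals.mean()) < 1e-10
        assert abs(residuals @ (y - y.mean())) < 1e-8

    def test_constant_axis_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_out_axis([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_cohens_d_uses_pooled_sd():
    assert cohens_d([0, 0, 2, 2], [1, 1, 3, 3]) == pytest.approx(-1 / np.sqrt(4 / 3))
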