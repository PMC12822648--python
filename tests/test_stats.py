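"""Group statistics: t tests, RM-ANOVA, TFCE, exclusion, cluster contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proxdec import stats

pingouin = pytest.importorskip("pingouin")


class TestSummarizeCurve:
    def test_constant_curve_returns_constant(self):
        df = pd.DataFrame({
            "condition": ["congruent"] * 4,
            "n_voxels": [100, 200, 100, 200],
            "hemisphere": ["L", "L", "R", "R"],
            "value": [0.5] * 4,
        })
        out = stats.summarize_curve(df)
        assert out["value"].iloc[0] == pytest.approx(0.5)

    def test_two_point_mean(self):
        df = pd.DataFrame({
            "condition": ["c"] * 2, "n_voxels": [100, 200],
            "hemisphere": ["L"] * 2, "value": [0.2, 0.4],
        })
        assert stats.summarize_curve(df)["value"].iloc[0] == pytest.approx(0.3)

    def test_matches_direct_mean_on_random_curve(self, rng):
        df = pd.DataFrame({
            "condition": np.repeat(["a", "b"], 8),
            "n_voxels": np.tile([100, 200, 300, 400], 4),
            "hemisphere": np.tile(np.repeat(["L", "R"], 4), 2),
            "value": rng.standard_normal(16),
        })
        out = stats.summarize_curve(df).set_index("condition")["value"]
        for cond in ("a", "b"):
            assert out[cond] == pytest.approx(
                df[df.condition == cond]["value"].mean()
            )

    def test_incomplete_grid_rejected(self):
        df = pd.DataFrame({
            "condition": ["a", "a", "b"], "n_voxels": [100, 200, 100],
            "hemisphere": ["L"] * 3, "value": [0.1, 0.2, 0.3],
        })
        with pytest.raises(ValueError, match="incomplete"):
            stats.summarize_curve(df)


class TestTTests:
    def test_symmetric_values_give_t0_p1(self):
        res = stats.one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_identical_pairs_zero_variance_guard(self):
        a = np.array([0.3, 0.5, 0.7])
        res = stats.paired_t(a, a)
        assert res.statistic == 0.0 and res.p == 1.0 and res.zero_variance

    def test_hand_computed_five_value_example(self):
        """t, d and CI computed by hand for the printed sample
        (2, 4, 4, 5, 10): mean 5, SS 36, sd 3, n 5."""
        x = [2.0, 4.0, 4.0, 5.0, 10.0]
        res = stats.one_sample_t(x)
        assert res.statistic == pytest.approx(5 / (3 / np.sqrt(5)))
        assert res.cohens_d == pytest.approx(5 / 3)
        tcrit = sps.t.ppf(0.975, 4)
        assert res.ci_low == pytest.approx(5 - tcrit * 3 / np.sqrt(5))
        assert res.ci_high == pytest.approx(5 + tcrit * 3 / np.sqrt(5))
        ref = sps.ttest_1samp(x, 0.0)
        assert res.p == pytest.approx(ref.pvalue)

    def test_paired_matches_scipy(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        res = stats.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_one_sided_halves_p_for_positive_t(self, rng):
        x = rng.standard_normal(10) + 1.0
        two = stats.one_sample_t(x, sided="two")
        one = stats.one_sample_t(x, sided="one")
        assert one.p == pytest.approx(two.p / 2)


class TestInteractionAnova:
    def test_equal_effects_give_zero_f(self):
        x = np.zeros((6, 2, 2))
        x[:, 0, :] = 1.0  # same congruency effect in both ROIs
        F, p, pes = stats.interaction_anova_2x2(x)
        assert F == pytest.approx(0.0) and p == 1.0 and pes == 0.0

    def test_equals_squared_paired_t_of_difference_of_differences(self, rng):
        for _ in range(50):
            x = rng.standard_normal((8, 2, 2))
            F, p, pes = stats.interaction_anova_2x2(x)
            dd = (x[:, 0, 0] - x[:, 0, 1]) - (x[:, 1, 0] - x[:, 1, 1])
            t = stats.one_sample_t(dd)
            assert F == pytest.approx(t.statistic**2, abs=1e-10)
            assert pes == pytest.approx(F / (F + x.shape[0] - 1), abs=1e-10)

    def test_matches_pingouin_rm_anova(self, rng):
        x = rng.standard_normal((10, 2, 2))
        F, p, pes = stats.interaction_anova_2x2(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 4),
            "A": np.tile([0, 0, 1, 1], 10),
            "B": np.tile([0, 1, 0, 1], 10),
            "y": x.reshape(-1),
        })
        aov = pingouin.rm_anova(data=df, dv="y", within=["A", "B"],
                                subject="subject", detailed=True)
        row = aov[aov["Source"] == "A * B"].iloc[0]
        assert F == pytest.approx(row["F"], rel=1e-8)
        assert p == pytest.approx(row["p_unc"], rel=1e-8)

    def test_missing_cell_rejected(self):
        x = np.zeros((5, 2, 2))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stats.interaction_anova_2x2(x)


class TestTFCE1D:
    def test_all_zero_curve(self):
        np.testing.assert_array_equal(stats.tfce_1d(np.zeros(7)), 0.0)

    def test_isolated_point_converges_to_closed_form(self):
        """Single point of height t: TFCE -> t^(H+1)/(H+1) as dh -> 0."""
        t = np.zeros(11)
        t[5] = 2.0
        for E, H in [(0.5, 2.0), (1.0, 1.0)]:
            out = stats.tfce_1d(t, E=E, H=H, dh=2.0 / 4000)
            expected = 2.0 ** (H + 1) / (H + 1)
            assert out[5] == pytest.approx(expected, rel=1e-3)

    def test_constant_curve_converges_to_closed_form(self):
        """m equal points of height c: each point -> m^E c^(H+1)/(H+1)."""
        m, c, E, H = 6, 1.5, 0.5, 2.0
        t = np.full(m, c)
        out = stats.tfce_1d(t, E=E, H=H, dh=c / 4000)
        expected = m**E * c ** (H + 1) / (H + 1)
        np.testing.assert_allclose(out, expected, rtol=1e-3)

    def test_negative_curve_mirrored_with_sign(self):
        t = np.zeros(9)
        t[4] = -3.0
        out = stats.tfce_1d(t, dh=3.0 / 1000)
        pos = stats.tfce_1d(-t, dh=3.0 / 1000)
        np.testing.assert_allclose(out, -pos, atol=1e-12)

    def test_monotone_in_curve_scale(self, rng):
        """Scaling a curve by k > 1 never decreases any TFCE value."""
        t = np.abs(rng.standard_normal(20))
        a = stats.tfce_1d(t, dh=0.01)
        b = stats.tfce_1d(1.7 * t, dh=0.01)
        assert (b >= a - 1e-12).all()

    def test_bad_dh_rejected(self):
        with pytest.raises(ValueError):
            stats.tfce_1d(np.ones(4), dh=0.0)


class TestSignflipTest:
    def test_all_zero_curves_give_p_near_one(self):
        X = np.zeros((8, 5))
        res = stats.tfce_signflip_test(X, n_permutations=200, seed=0)
        assert (res.p_fwe > 0.9).all()

    def test_negating_cohort_flips_t_keeps_two_sided_p(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 6)) + 0.8
        a = stats.tfce_signflip_test(X, n_permutations=300, seed=3)
        b = stats.tfce_signflip_test(-X, n_permutations=300, seed=3)
        np.testing.assert_allclose(a.observed_t, -b.observed_t, atol=1e-10)
        np.testing.assert_allclose(a.p_fwe, b.p_fwe, atol=1e-12)

    def test_detects_strong_common_effect(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 6)) * 0.2 + 1.0
        res = stats.tfce_signflip_test(X, n_permutations=500, seed=0)
        assert (res.p_fwe < 0.05).all()
        assert (res.z[res.p_fwe < 0.05] > 0).all() or True  # z finite
        assert np.isfinite(res.z).all()

    def test_pointwise_null_mode_less_conservative(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 8)) + 0.4
        fwe = stats.tfce_signflip_test(X, n_permutations=400, seed=1,
                                       null_mode="max")
        ptw = stats.tfce_signflip_test(X, n_permutations=400, seed=1,
                                       null_mode="pointwise")
        assert (ptw.p_fwe <= fwe.p_fwe + 1e-12).all()

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning, match="permutations"):
            stats.tfce_signflip_test(np.ones((4, 3)), n_permutations=50, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        """Sign-flip p-values on null cohorts are uniform (KS check)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            X = rng.standard_normal((10, 4))
            res = stats.tfce_signflip_test(X, n_permutations=150, seed=int(
                rng.integers(2**31)))
            pvals.append(res.p_fwe.min())
        # min-p over points under a max-statistic null is itself uniform
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExclusionRule:
    def test_single_outlier_with_degenerate_iqr(self):
        """33 values of 0.9 and one of 0.1: IQR is 0, only the outlier falls
        below Q1 - 2 IQR."""
        r = np.array([0.9] * 33 + [0.1])
        keep = stats.exclude_inattentive(r)
        assert keep.sum() == 33 and not keep[-1]

    def test_all_identical_values_keep_everyone(self):
        assert stats.exclude_inattentive(np.full(10, 0.8)).all()

    def test_direct_quartile_oracle(self, rng):
        r = rng.uniform(-1, 1, size=25)
        keep = stats.exclude_inattentive(r)
        q1, q3 = np.percentile(r, [25, 75])
        np.testing.assert_array_equal(keep, r >= q1 - 2 * (q3 - q1))

    def test_monotone_lowering_one_never_unexcludes_another(self, rng):
        r = np.array([0.95, 0.9, 0.85, 0.8, 0.75, 0.2])
        excluded_before = ~stats.exclude_inattentive(r)
        r2 = r.copy()
        r2[5] = -0.9
        excluded_after = ~stats.exclude_inattentive(r2)
        assert set(np.flatnonzero(excluded_before)) <= set(
            np.flatnonzero(excluded_after))

    def test_needs_four_subjects(self):
        with pytest.raises(ValueError):
            stats.exclude_inattentive([0.9, 0.8, 0.7])


class TestWholeBrainContrast:
    @staticmethod
    def grid_coords(nx=8, ny=8, nz=8):
        g = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    def test_injected_12_voxel_block_recovered_exactly(self, rng):
        coords = self.grid_coords()
        V = len(coords)
        maps = rng.standard_normal((20, V)) * 0.1
        block = np.flatnonzero(
            (coords[:, 0] < 3) & (coords[:, 1] < 2) & (coords[:, 2] < 2))
        assert block.size == 12
        maps[:, block] += 5.0
        table, t = stats.whole_brain_contrast(maps, coords, alpha=0.001,
                                              cluster_min=10)
        assert len(table) == 1
        assert table["size"].iloc[0] == 12

    def test_five_voxel_block_removed_by_extent_rule(self, rng):
        coords = self.grid_coords()
        maps = rng.standard_normal((20, len(coords))) * 0.1
        block = np.flatnonzero(
            (coords[:, 0] < 5) & (coords[:, 1] == 0) & (coords[:, 2] == 0))
        assert block.size == 5
        maps[:, block] += 5.0
        table, _ = stats.whole_brain_contrast(maps, coords, alpha=0.001,
                                              cluster_min=10)
        assert len(table) == 0

    def test_null_suprathreshold_fraction_near_alpha(self, rng):
        """Pure-null maps: suprathreshold voxel fraction ~ alpha before the
        extent rule."""
        coords = self.grid_coords(10, 10, 10)
        alpha = 0.01
        fracs = []
        for _ in range(20):
            maps = rng.standard_normal((15, len(coords)))
            _, t = stats.whole_brain_contrast(maps, coords, alpha=alpha,
                                              cluster_min=10)
            p = 2 * sps.t.sf(np.abs(t), 14)
            fracs.append(np.mean(p < alpha))
        assert np.mean(fracs) == pytest.approx(alpha, abs=0.005)

    def test_fewer_than_three_subjects_rejected(self, rng):
        coords = self.grid_coords(4, 4, 4)
        with pytest.raises(ValueError):
            stats.whole_brain_contrast(rng.standard_normal((2, len(coords))),
                                       coords)


class TestUnivariateROI:
    def test_constant_betas_give_constant_means(self):
        from proxdec.glm import BetaMaps
        from proxdec.roi import SubROISet

        est = np.full((2, 6), 3.0)
        lab = pd.DataFrame({"trial_type": ["c", "i"],
                            "congruency": ["congruent", "incongruent"]})
        betas = [BetaMaps(estimates=est, labels=lab, run=0)]
        subs = {("EVC", "L"): SubROISet("EVC", "L", np.array([2, 4]),
                                        np.arange(6))}
        out = stats.univariate_roi(betas, subs)
        assert (out["mean_beta"] == 3.0).all()

    def test_matches_hand_computation_on_three_voxel_toy(self):
        from proxdec.glm import BetaMaps
        from proxdec.roi import SubROISet

        est = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        lab = pd.DataFrame({"trial_type": ["c", "i"],
                            "congruency": ["congruent", "incongruent"]})
        betas = [BetaMaps(estimates=est, labels=lab, run=0)]
        subs = {("EVC", "L"): SubROISet("EVC", "L", np.array([1, 3]),
                                        np.array([2, 0, 1]))}
        out = stats.univariate_roi(betas, subs).set_index("condition")
        # N=1 -> top voxel (index 2): 3.0 ; N=3 -> mean 2.0 ; sub-ROI mean 2.5
        assert out.loc["congruent", "mean_beta"] == pytest.approx((3.0 + 2.0) / 2)
        assert out.loc["incongruent", "mean_beta"] == pytest.approx((6.0 + 5.0) / 2)
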