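"""Classifier information and the two cross-decoding schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proxdec import decoding, design, glm, roi, simulate
from proxdec.simulate import TruthParams


class TestZscoreFeatures:
    def test_two_point_standardization(self):
        Z = decoding.zscore_features(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1.0, 1.0])

    def test_constant_column_zeroed_and_flagged(self):
        X = np.array([[2.0, 1.0], [2.0, 3.0], [2.0, 5.0]])
        Z, flags = decoding.zscore_features(X, return_flags=True)
        np.testing.assert_array_equal(Z[:, 0], 0.0)
        assert flags.tolist() == [True, False]

    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((10, 4))
        Z = decoding.zscore_features(X)
        np.testing.assert_allclose(Z, (X - X.mean(0)) / X.std(0), atol=1e-12)
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0), 1.0, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            decoding.zscore_features(np.ones((1, 3)))


class TestClassifierInformation:
    def test_perfect_two_sample_separation_is_one(self):
        assert decoding.classifier_information(
            [2.0, -2.0], [1.0, -1.0]
        ) == pytest.approx(1.0)

    def test_constant_distances_guarded_to_zero(self):
        value, flag = decoding.classifier_information(
            [1.5, 1.5, 1.5], [1, -1, 1], return_flag=True
        )
        assert value == 0.0 and flag

    def test_null_mean_within_monte_carlo_error(self, rng):
        """Distances independent of labels: mean over 10,000 draws within
        3 SE of 0."""
        vals = np.empty(10_000)
        labels = np.repeat([1.0, -1.0], 5)
        for i in range(vals.size):
            vals[i] = decoding.classifier_information(
                rng.standard_normal(10), labels
            )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_mismatched_lengths_and_bad_labels(self):
        with pytest.raises(ValueError):
            decoding.classifier_information([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            decoding.classifier_information([1.0, 2.0], [1.0, 0.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**32 - 1))
    def test_invariant_to_positive_rescaling(self, scale, seed):
        r = np.random.default_rng(seed)
        d = r.standard_normal(8)
        labels = np.where(r.random(8) < 0.5, 1.0, -1.0)
        if np.unique(labels).size < 2 or d.std() == 0:
            return
        a = decoding.classifier_information(d, labels)
        b = decoding.classifier_information(scale * d, labels)
        assert a == pytest.approx(b, abs=1e-10)

    def test_label_permutation_null_symmetric(self, rng):
        """The permutation distribution of CI is symmetric about 0."""
        d = rng.standard_normal(12)
        labels = np.repeat([1.0, -1.0], 6)
        vals = np.array([
            decoding.classifier_information(d, rng.permutation(labels))
            for _ in range(4000)
        ])
        assert abs(np.mean(vals)) < 3 * vals.std(ddof=1) / np.sqrt(vals.size)
        q = np.quantile(vals, [0.1, 0.9])
        assert abs(q[0] + q[1]) < 0.1  # mirrored tails


def _analyze(params, sd, meta, counts):
    """GLM + ROI + betas for one subject (helper for scheme tests)."""
    loc = [glm.fit_glm(r.data, glm.build_design_matrix(
        e, n_volumes=params.localizer_run_volumes), run=i)
        for i, (r, e) in enumerate(zip(sd.localizer_runs, sd.design.localizer_runs))]
    t, _ = roi.localizer_tmap(loc)
    subrois = roi.make_subrois(t, meta, counts=counts)
    train = [glm.fit_glm(r.data, glm.build_design_matrix(
        e, n_volumes=params.training_run_volumes, per_event=True), run=i)
        for i, (r, e) in enumerate(zip(sd.training_runs, sd.design.training_runs))]
    main = [glm.fit_glm(r.data, glm.build_design_matrix(
        e, n_volumes=params.run_length_volumes), run=i)
        for i, (r, e) in enumerate(zip(sd.main_runs, sd.design.main_runs))]
    return subrois, train, main


class TestCrossDecodeExp1:
    def test_noiseless_ceiling_identical_across_conditions(self, tiny_params,
                                                           tiny_meta):
        """Without noise and with equal gains, both conditions reach the same
        (maximal) information for the pooled test-set size."""
        tp = TruthParams(noise_sigma=0.0, amp_shape=1.0, amp_background=0.3,
                         gain_congruent=1.0, gain_incongruent=1.0,
                         surprise_amplitude=0.0)
        sd = simulate.simulate_subject(tiny_params, tp, tiny_meta, seed=0)
        counts = np.array([40, 80])
        subrois, train, main = _analyze(tiny_params, sd, tiny_meta, counts)
        df = decoding.cross_decode_exp1(train, main, subrois)
        piv = df[df.direction == "forward"].groupby("condition").value.mean()
        assert piv["congruent"] == pytest.approx(piv["incongruent"], abs=1e-6)
        assert piv["congruent"] > 0.9

    def test_direction_mean_is_arithmetic_average(self, tiny_subject, tiny_params,
                                                  tiny_meta):
        counts = np.array([40, 80])
        subrois, train, main = _analyze(tiny_params, tiny_subject, tiny_meta, counts)
        df = decoding.cross_decode_exp1(train, main, subrois)
        piv = df.pivot_table(index=["roi", "hemisphere", "n_voxels", "condition"],
                             columns="direction", values="value")
        np.testing.assert_allclose(
            piv["mean"], (piv["forward"] + piv["reverse"]) / 2, atol=1e-12
        )
        # bounded by the two directions
        assert (piv["mean"] <= np.maximum(piv["forward"], piv["reverse"]) + 1e-12).all()
        assert (piv["mean"] >= np.minimum(piv["forward"], piv["reverse"]) - 1e-12).all()

    def test_congruency_gain_orders_conditions(self, tiny_params, tiny_meta):
        """Generator congruent > incongruent gain yields a positive mean
        congruent-incongruent difference across simulated subjects."""
        tp = TruthParams(amp_shape=0.08, amp_background=0.04,
                         gain_congruent=1.5, gain_incongruent=0.5,
                         surprise_amplitude=0.0)
        counts = np.array([40, 80])
        diffs = []
        for seed in range(8):
            sd = simulate.simulate_subject(tiny_params, tp, tiny_meta, seed=seed)
            subrois, train, main = _analyze(tiny_params, sd, tiny_meta, counts)
            df = decoding.cross_decode_exp1(train, main, subrois)
            m = df[(df.direction == "mean") & (df.roi == "EVC")]
            piv = m.groupby("condition").value.mean()
            diffs.append(piv["congruent"] - piv["incongruent"])
        assert np.mean(diffs) > 0

    def test_information_nondecreasing_in_generator_snr(self, tiny_params,
                                                        tiny_meta):
        """Mean classifier information over simulated subjects is
        non-decreasing across zero / low / high pattern-amplitude levels."""
        counts = np.array([40, 80])
        means = []
        for amp in (0.0, 0.05, 0.5):
            tp = TruthParams(amp_shape=amp, amp_background=amp / 2,
                             gain_congruent=1.0, gain_incongruent=1.0,
                             surprise_amplitude=0.0)
            vals = []
            for seed in range(8):
                sd = simulate.simulate_subject(tiny_params, tp, tiny_meta,
                                               seed=seed)
                subrois, train, main = _analyze(tiny_params, sd, tiny_meta,
                                                counts)
                df = decoding.cross_decode_exp1(train, main, subrois)
                vals.append(df[df.direction == "mean"].value.mean())
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > 0.5  # high-SNR level is far above chance

    def test_missing_split_raises(self, tiny_subject, tiny_params, tiny_meta):
        counts = np.array([40])
        subrois, train, main = _analyze(tiny_params, tiny_subject, tiny_meta, counts)
        broken = [b for b in main]
        for b in broken:
            keep = ~((b.labels["split_id"] == 2)
                     & (b.labels["congruency"] == "congruent"))
            b.estimates = b.estimates[keep.to_numpy()]
            b.labels = b.labels[keep.to_numpy()].reset_index(drop=True)
        with pytest.raises(ValueError, match="split 2"):
            decoding.cross_decode_exp1(train, broken, subrois)


class TestCrossDecodeExp2:
    @pytest.fixture(scope="class")
    def exp2_data(self, tiny_params_exp2):
        meta = simulate.make_voxel_meta(80)
        tp = TruthParams(amp_shape=0.15, amp_background=0.0,
                         occluded_signal_gain=0.8)
        sd = simulate.simulate_subject(tiny_params_exp2, tp, meta, seed=2)
        counts = np.array([40, 80])
        subrois, train, main = _analyze(tiny_params_exp2, sd, meta, counts)
        return subrois, train, main

    def test_output_shape_and_condition_label(self, exp2_data):
        subrois, train, main = exp2_data
        df = decoding.cross_decode_exp2(train, main, subrois)
        assert set(df["condition"]) == {"occluded"}
        assert set(df["direction"]) == {"forward", "reverse", "mean"}
        assert len(df) == 4 * 2 * 3  # roi x hemi combos x counts x directions

    def test_catch_trials_never_enter_test_set(self, exp2_data, tiny_params_exp2,
                                               tiny_meta):
        subrois, train, main = exp2_data
        for bm in main:
            tt = bm.labels["trial_type"]
            assert "catch" in set(tt) or "catch_reappearance" in set(tt)
        # decoding uses only the wide/narrow rows
        df = decoding.cross_decode_exp2(train, main, subrois)
        assert np.isfinite(df["value"]).all()

    def test_zero_occluded_gain_is_chance(self, tiny_params_exp2):
        """occluded_signal_gain = 0: group-mean information within 3 SE of 0."""
        meta = simulate.make_voxel_meta(60)
        tp = TruthParams(amp_shape=0.1, occluded_signal_gain=0.0)
        counts = np.array([30, 60])
        vals = []
        for seed in range(10):
            sd = simulate.simulate_subject(tiny_params_exp2, tp, meta, seed=seed)
            subrois, train, main = _analyze(tiny_params_exp2, sd, meta, counts)
            df = decoding.cross_decode_exp2(train, main, subrois)
            vals.append(df[df.direction == "mean"].value.mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.02


class TestTimeResolvedDecode:
    def test_ten_bins_in_ten_values_out(self, tiny_subject, tiny_params, tiny_meta):
        train = [glm.fit_glm(r.data, glm.build_design_matrix(
            e, n_volumes=tiny_params.training_run_volumes, per_event=True), run=i)
            for i, (r, e) in enumerate(zip(tiny_subject.training_runs,
                                           tiny_subject.design.training_runs))]
        fir = [glm.fit_fir(r.data, e, n_bins=10, run=i)
               for i, (r, e) in enumerate(zip(tiny_subject.main_runs,
                                              tiny_subject.design.main_runs))]
        out = decoding.time_resolved_decode(train, fir, np.arange(60), n_bins=10)
        assert len(out) == 20  # 10 bins x 2 conditions
        assert sorted(out["bin"].unique().tolist()) == list(range(10))

    def test_bin_count_mismatch_raises(self, tiny_subject, tiny_params):
        train = [glm.fit_glm(r.data, glm.build_design_matrix(
            e, n_volumes=tiny_params.training_run_volumes, per_event=True), run=i)
            for i, (r, e) in enumerate(zip(tiny_subject.training_runs,
                                           tiny_subject.design.training_runs))]
        fir = [glm.fit_fir(r.data, e, n_bins=8, run=i)
               for i, (r, e) in enumerate(zip(tiny_subject.main_runs,
                                              tiny_subject.design.main_runs))]
        with pytest.raises(ValueError, match="bins"):
            decoding.time_resolved_decode(train, fir, np.arange(40), n_bins=10)

    def test_information_peaks_where_signal_is(self, tiny_params, tiny_meta):
        """The information time course peaks in the bins where the (HRF-shaped)
        response to the decoded events is strongest (bins ~4-7)."""
        tp = TruthParams(amp_shape=0.4, amp_background=0.0,
                         gain_congruent=1.0, gain_incongruent=1.0,
                         surprise_amplitude=0.0)
        sd = simulate.simulate_subject(tiny_params, tp, tiny_meta, seed=9)
        train = [glm.fit_glm(r.data, glm.build_design_matrix(
            e, n_volumes=tiny_params.training_run_volumes, per_event=True), run=i)
            for i, (r, e) in enumerate(zip(sd.training_runs,
                                           sd.design.training_runs))]
        fir = [glm.fit_fir(r.data, e, n_bins=10, run=i)
               for i, (r, e) in enumerate(zip(sd.main_runs, sd.design.main_runs))]
        out = decoding.time_resolved_decode(train, fir, np.arange(160), n_bins=10)
        curve = out[out.condition == "congruent"].sort_values("bin").value.to_numpy()
        assert 3 <= int(np.argmax(curve)) <= 7
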