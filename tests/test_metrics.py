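"""Correlation structure, responses, responsiveness and interneuron masks."""

import numpy as np
import pytest

from neodev.io import FluorescenceRecording, StimulusLog, ValidationError
from neodev.metrics import (
    cell_neuropil_correlation,
    correlation_vs_distance,
    cumulative_dff_comparison,
    identify_interneurons,
    pairwise_correlations,
    response_amplitude,
    responsiveness_test,
    stimulus_triggered_average,
)
from neodev.simulate import SimConfig, simulate_recording, simulate_red_recording

from conftest import make_dff


class TestPairwiseCorrelations:
    def test_identical_and_negated_traces(self):
        t = np.sin(np.linspace(0, 10, 100))
        dff = make_dff([t, t, -t])
        corr = pairwise_correlations(dff)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_hand_computed_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        dff = make_dff([x, y, 2 * x + 1, np.array([5.0, 1.0, 1.0, 5.0])])
        corr = pairwise_correlations(dff)
        # textbook Pearson for x vs y
        r = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert corr[0, 1] == pytest.approx(r)
        assert corr[0, 2] == pytest.approx(1.0)  # affine rescaling

    def test_zero_variance_cell_excluded_not_fatal(self):
        dff = make_dff([np.ones(50), np.sin(np.linspace(0, 5, 50)), np.cos(np.linspace(0, 5, 50))])
        corr = pairwise_correlations(dff)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])
        assert np.isfinite(corr[1, 2])

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_correlations(make_dff(np.ones((3, 10))))


class TestCorrelationVsDistance:
    def test_close_identical_pair(self):
        t = np.sin(np.linspace(0, 10, 100))
        dff = make_dff([t, t], coords=[[0.0, 0.0], [10.0, 0.0]])
        cbd = correlation_vs_distance(pairwise_correlations(dff), dff.coords, 40.0)
        assert cbd.mean_correlation[0] == pytest.approx(1.0)
        assert cbd.pair_counts[0] == 1

    def test_empty_first_bin_flagged_missing(self):
        t = np.sin(np.linspace(0, 10, 100))
        rng = np.random.default_rng(0)
        dff = make_dff([t, t + rng.normal(0, 1, 100)], coords=[[0.0, 0.0], [50.0, 0.0]])
        cbd = correlation_vs_distance(pairwise_correlations(dff), dff.coords, 40.0)
        assert np.isnan(cbd.mean_correlation[0])
        assert cbd.pair_counts[0] == 0
        assert cbd.pair_counts[1] == 1


class TestCumulativeComparison:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=500)
        _, _, ks, _ = cumulative_dff_comparison(x, x)
        assert ks == 0.0

    def test_unit_shift_of_standard_normal(self):
        # max |Phi(x) - Phi(x-1)| = 2*Phi(1/2) - 1 ~ 0.383
        rng = np.random.default_rng(1)
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000) + 1.0
        _, _, ks, p = cumulative_dff_comparison(a, b)
        assert ks == pytest.approx(0.383, abs=0.03)
        assert p < 1e-6

    def test_left_shift_raises_cdf_pointwise(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=2000)
        b = a - 0.5  # left-shifted (hypoactive) sample
        (xa, fa), (xb, fb), _, _ = cumulative_dff_comparison(a, b)
        grid = np.linspace(-2, 2, 50)
        cdf_a = np.searchsorted(xa, grid) / xa.size
        cdf_b = np.searchsorted(xb, grid) / xb.size
        assert np.all(cdf_b >= cdf_a)


class TestStimulusTriggeredAverage:
    def test_planted_response_recovered_exactly(self):
        n_frames = 3000
        kernel = np.concatenate([np.zeros(0), np.linspace(1, 0, 30)])
        dff = np.zeros((3, n_frames))
        onsets = [300, 900, 1500, 2100]
        for o in onsets:
            dff[:, o:o + 30] += kernel[None, :]
        rec = make_dff(dff)
        log = StimulusLog([(o, "airpuff") for o in onsets])
        sta = stimulus_triggered_average(rec, log, pre_s=1.0, post_s=2.0)["airpuff"]
        post = sta["mean"][30:60]
        np.testing.assert_allclose(post, kernel, atol=1e-12)
        np.testing.assert_allclose(sta["mean"][:30], 0.0, atol=1e-12)

    def test_edge_trials_dropped(self):
        rec = make_dff(np.zeros((2, 300)))
        log = StimulusLog([(5, "airpuff"), (150, "airpuff")])
        sta = stimulus_triggered_average(rec, log, pre_s=1.0, post_s=2.0)
        assert sta["airpuff"]["n_trials"] == 1

    def test_no_valid_trials_rejected(self):
        rec = make_dff(np.zeros((2, 100)))
        log = StimulusLog([(5, "airpuff")])
        with pytest.raises(ValidationError):
            stimulus_triggered_average(rec, log, pre_s=2.0, post_s=2.0)


class TestResponseAmplitude:
    def test_boxcar_height_recovered(self):
        dff = np.zeros((1, 2000))
        dff[0, 320:350] = 0.7
        rec = make_dff(dff)
        log = StimulusLog([(300, "single_whisker")])
        amp = response_amplitude(rec, log, window_s=20.0)["single_whisker"]
        assert amp[0, 0] == pytest.approx(0.7)

    def test_flat_trace_zero(self):
        rec = make_dff(np.zeros((1, 2000)))
        log = StimulusLog([(300, "airpuff")])
        assert response_amplitude(rec, log)["airpuff"][0, 0] == 0.0

    def test_peak_outside_window_excluded(self):
        fr = 30.0
        dff = np.zeros((1, 2000))
        dff[0, 400] = 0.2                      # inside the 20 s window
        dff[0, 300 + int(21 * fr)] = 5.0       # 21 s after onset: excluded
        rec = make_dff(dff, frame_rate=fr)
        log = StimulusLog([(300, "airpuff")])
        assert response_amplitude(rec, log, window_s=20.0)["airpuff"][0, 0] == pytest.approx(0.2)


class TestResponsiveness:
    @staticmethod
    def _recording(n_cells, n_trials, shift, noise_sd, seed, fr=30.0):
        rng = np.random.default_rng(seed)
        isi = int(25 * fr)
        n_frames = (n_trials + 1) * isi
        dff = rng.normal(0, noise_sd, size=(n_cells, n_frames))
        onsets = [(i + 1) * isi for i in range(n_trials)]
        for o in onsets:
            dff[:, o:o + int(fr)] += shift
        return make_dff(dff, fr), StimulusLog([(o, "airpuff") for o in onsets])

    def test_shifted_cells_detected(self):
        rec, log = self._recording(20, 10, shift=1.0, noise_sd=0.05, seed=3)
        res = responsiveness_test(rec, log)["airpuff"]
        assert res.recruitment == 1.0
        assert (res.p_adjusted >= res.p_raw).all()

    def test_null_cells_controlled(self):
        rec, log = self._recording(200, 10, shift=0.0, noise_sd=0.1, seed=4)
        res = responsiveness_test(rec, log)["airpuff"]
        assert (res.p_raw < 0.05).mean() <= 0.1   # raw false positives near alpha
        assert res.recruitment <= 0.05            # BH keeps discoveries rare

    def test_single_trial_rejected(self):
        rec, log = self._recording(2, 1, shift=0.0, noise_sd=0.1, seed=5)
        with pytest.raises(ValidationError, match="trials"):
            responsiveness_test(rec, log)


class TestInterneurons:
    def test_three_bright_cells_flagged(self):
        raw = np.ones((100, 20))
        raw[[4, 40, 77]] = 100.0
        rec = FluorescenceRecording(raw, np.zeros((100, 2)), 30.0, "red")
        mask = identify_interneurons(rec)
        assert set(np.nonzero(mask)[0]) == {4, 40, 77}

    def test_all_identical_cells_all_flagged(self):
        rec = FluorescenceRecording(np.ones((10, 20)), np.zeros((10, 2)), 30.0, "red")
        assert identify_interneurons(rec).all()

    def test_mask_size_on_continuous_values(self):
        rng = np.random.default_rng(6)
        for n in (50, 100, 333):
            raw = rng.uniform(1, 10, size=(n, 5))
            rec = FluorescenceRecording(raw, np.zeros((n, 2)), 30.0, "red")
            k = int(identify_interneurons(rec).sum())
            assert abs(k - int(np.ceil(0.03 * n))) <= 1

    def test_ground_truth_recovery_high_contrast(self):
        # 3% of 200 is integral, so the planted count equals the percentile cut
        cfg = SimConfig(seed=8, n_cells=200, duration_s=30)
        rec, truth = simulate_recording(cfg)
        red = simulate_red_recording(cfg, rec.coords, truth.interneurons)
        got = identify_interneurons(red)
        np.testing.assert_array_equal(got, truth.interneurons)


class TestNeuropil:
    def test_identical_and_anticorrelated(self):
        t = np.sin(np.linspace(0, 20, 500))
        assert cell_neuropil_correlation(t, t) == pytest.approx(1.0)
        assert cell_neuropil_correlation(t, -t) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 10_000))
        assert abs(cell_neuropil_correlation(a, b)) < 0.05

    def test_zero_variance_gives_nan(self):
        assert np.isnan(cell_neuropil_correlation(np.ones(10), np.arange(10.0)))
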