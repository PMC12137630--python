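"""LSPS map conservation laws and PSC feature extraction."""

import numpy as np
import pytest

from neodev.io import ValidationError
from neodev.lsps import (
    LSPSMap,
    PSCFeatures,
    align_and_average_maps,
    columnar_profile,
    extract_psc_features,
    layer_input_sums,
    minimal_input_summary,
    normalize_map,
    read_lsps_map,
    write_lsps_map,
)
from neodev.simulate import simulate_psc_sweep

LAYERS = {"L2/3": (0, 4), "L4": (4, 6), "L5a": (6, 8), "L5b": (8, 10), "L6": (10, 11)}


def uniform_map(value=1.0):
    return LSPSMap(np.full((11, 17), value), layer_rows=dict(LAYERS))


class TestNormalize:
    def test_uniform_map_every_pixel_1_over_187(self):
        nm = normalize_map(uniform_map(3.0))
        np.testing.assert_allclose(nm.grid, 1.0 / 187.0)

    def test_single_nonzero_pixel(self):
        grid = np.zeros((11, 17))
        grid[5, 7] = 4.2
        nm = normalize_map(LSPSMap(grid, layer_rows=dict(LAYERS)))
        assert nm.grid[5, 7] == 1.0
        assert nm.grid.sum() == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = LSPSMap(rng.uniform(0, 5, (11, 17)), layer_rows=dict(LAYERS))
        once = normalize_map(m)
        twice = normalize_map(once)
        np.testing.assert_allclose(once.grid, twice.grid)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_map(LSPSMap(np.zeros((11, 17))))


class TestProfilesAndLayers:
    def test_profile_conserves_total(self):
        rng = np.random.default_rng(1)
        m = LSPSMap(rng.uniform(0, 2, (11, 17)), layer_rows=dict(LAYERS))
        assert columnar_profile(m).sum() == pytest.approx(m.grid.sum())
        nm = normalize_map(m)
        assert columnar_profile(nm).sum() == pytest.approx(1.0)

    def test_single_pixel_one_hot_profile(self):
        grid = np.zeros((11, 17))
        grid[8, 2] = 1.0
        profile = columnar_profile(LSPSMap(grid))
        assert profile[8] == 1.0 and profile.sum() == 1.0

    def test_planted_l5b_band_peaks_profile(self):
        grid = np.zeros((11, 17))
        grid[8:10, :] = 2.0
        profile = columnar_profile(LSPSMap(grid, layer_rows=dict(LAYERS)))
        assert set(np.argsort(profile)[-2:]) == {8, 9}

    def test_layer_sums_partition_total(self):
        rng = np.random.default_rng(2)
        m = LSPSMap(rng.uniform(0, 3, (11, 17)), layer_rows=dict(LAYERS))
        sums = layer_input_sums(m)
        assert sum(sums.values()) == pytest.approx(m.grid.sum())

    def test_planted_l5b_charge_isolated(self):
        grid = np.zeros((11, 17))
        grid[8, 3] = 1.5
        grid[9, 10] = 0.5
        sums = layer_input_sums(LSPSMap(grid, layer_rows=dict(LAYERS)))
        assert sums["L5b"] == pytest.approx(2.0)
        assert all(v == 0 for k, v in sums.items() if k != "L5b")

    def test_uniform_two_layer_ratio(self):
        m = LSPSMap(np.ones((11, 17)), layer_rows={"upper": (0, 4), "lower": (4, 11)})
        sums = layer_input_sums(m)
        assert sums["upper"] / sums["lower"] == pytest.approx(4 / 7)

    def test_uncovered_rows_rejected(self):
        m = LSPSMap(np.ones((11, 17)), layer_rows={"L4": (0, 5)})
        with pytest.raises(ValidationError, match="not assigned"):
            layer_input_sums(m)


class TestAlignment:
    def test_self_average_identical(self):
        rng = np.random.default_rng(3)
        m = LSPSMap(rng.uniform(0, 1, (11, 17)), layer_rows=dict(LAYERS))
        mean, counts = align_and_average_maps([m, m])
        np.testing.assert_allclose(mean, m.grid)
        assert (counts == 2).all()

    def test_offset_maps_average_over_overlap(self):
        rng = np.random.default_rng(4)
        content = rng.uniform(0, 1, (11, 17))
        a = LSPSMap(content, layer_rows={"L4": (4, 6)})
        b = LSPSMap(content, layer_rows={"L4": (5, 7)})  # boundary one row lower
        mean, counts = align_and_average_maps([a, b])
        assert mean.shape == (12, 17)
        # overlap rows hold the average of content shifted by one row
        np.testing.assert_allclose(mean[1:11], (content[1:] + content[:-1]) / 2)
        assert counts[0].max() == 1 and counts[5].min() == 2

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        maps = [
            LSPSMap(rng.uniform(0, 1, (11, 17)), layer_rows={"L4": (4, 6 + i)})
            for i in range(3)
        ]
        a, ca = align_and_average_maps(maps)
        b, cb = align_and_average_maps(maps[::-1])
        np.testing.assert_allclose(a, b)
        np.testing.assert_array_equal(ca, cb)

    def test_round_trip_csv(self, tmp_path):
        rng = np.random.default_rng(6)
        m = LSPSMap(rng.uniform(0, 1, (11, 17)), layer_rows=dict(LAYERS),
                    soma_position=(5, 8))
        path = write_lsps_map(m, tmp_path / "map.csv")
        back = read_lsps_map(path)
        np.testing.assert_allclose(back.grid, m.grid)
        assert back.layer_rows == m.layer_rows
        assert back.soma_position == (5, 8)


class TestPSC:
    def test_flat_sweep_is_failure(self):
        f = extract_psc_features(np.zeros(6000), 0.010)
        assert f.is_failure
        assert np.isnan(f.onset_latency_ms)

    def test_square_pulse_forced_arithmetic(self):
        sw = np.zeros(6000)
        sw[int(0.015 * 20000):int(0.025 * 20000)] = 100.0  # 100 pA x 10 ms at 5 ms latency
        f = extract_psc_features(sw, 0.010)
        assert not f.is_failure
        assert f.onset_latency_ms == pytest.approx(5.0, abs=0.05)
        assert f.peak_amplitude_pa == pytest.approx(100.0)
        assert f.charge_pc == pytest.approx(1.0, rel=1e-3)

    def test_event_outside_window_is_failure(self):
        sw = np.zeros(6000)
        start = int(0.010 * 20000) + int(0.060 * 20000)  # 60 ms post-stimulus
        sw[start:start + 200] = 100.0
        f = extract_psc_features(sw, 0.010, window_ms=(0.0, 50.0))
        assert f.is_failure

    def test_inward_current_polarity(self):
        sw = np.zeros(6000)
        sw[int(0.015 * 20000):int(0.025 * 20000)] = -80.0
        f = extract_psc_features(sw, 0.010)
        assert f.polarity == -1
        assert f.peak_amplitude_pa == pytest.approx(80.0)

    def test_planted_double_exponential_recovery(self):
        # SNR >= 5 regime with a realistic 100 ms pre-stimulus baseline
        rng = np.random.default_rng(7)
        onset_errs, charge_errs = [], []
        for i in range(20):
            amp = 200.0
            sweep, true_q = simulate_psc_sweep(
                amp, onset_ms=5.0 + i, stim_onset_ms=100.0, sweep_ms=400.0,
                noise_sd_pa=amp / 10.0, rng=rng,
            )
            f = extract_psc_features(sweep, 0.100, window_ms=(0.0, 50.0))
            assert not f.is_failure
            onset_errs.append(abs(f.onset_latency_ms - (5.0 + i)))
            charge_errs.append(abs(f.charge_pc - true_q) / true_q)
        assert np.mean(onset_errs) <= 0.5
        assert np.mean(charge_errs) <= 0.05


class TestMinimalInput:
    def _features(self, n_fail, n_ok):
        fail = [PSCFeatures(0.0, 0.0, float("nan"), True, 0)] * n_fail
        ok = [PSCFeatures(50.0 + i, 0.5 + 0.1 * i, 4.0, False, -1) for i in range(n_ok)]
        return fail + ok

    def test_half_failures(self):
        s = minimal_input_summary(self._features(3, 3))
        assert s["failure_rate"] == 0.5

    def test_all_failures(self):
        s = minimal_input_summary(self._features(6, 0))
        assert s["failure_rate"] == 1.0
        assert np.isnan(s["mean_amplitude_pa"])

    def test_no_failures(self):
        s = minimal_input_summary(self._features(0, 6))
        assert s["failure_rate"] == 0.0
        assert s["mean_amplitude_pa"] == pytest.approx(np.mean([50, 51, 52, 53, 54, 55]))

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValidationError, match=">= 6"):
            minimal_input_summary(self._features(2, 2))
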