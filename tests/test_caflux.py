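"""Ca2+ line-scan analysis: baseline, dF/F0, spark detection, transients,
coupling fidelity, and SR-content estimation."""

import numpy as np
import pytest
from scipy import stats

from dyadkit import caflux
from dyadkit.io import LineScanKymograph
from dyadkit.simulate import ScanSimConfig, make_linescan
from dyadkit.simulate.linescan import _temporal_kernel

PX, DT = 0.1, 3.78  # um/pixel, ms/line


def _kymo(pixels):
    return LineScanKymograph(pixels=pixels, pixel_size_um=PX, line_interval_ms=DT)


def _spark_field(rng, n_space=200, n_time=800, amp=1.0, pos_um=10.0,
                 t0_s=1.0, noise_sd=0.1, fwhm_um=2.0):
    """dF/F0 field with one spark kernel plus Gaussian noise."""
    x = (np.arange(n_space) + 0.5) * PX
    t = (np.arange(n_time) + 0.5) * DT / 1000.0
    sig = fwhm_um / 2.355
    g = _temporal_kernel(t, t0_s, 8.0, 30.0)
    dff = amp * np.exp(-((x - pos_um) ** 2) / (2 * sig ** 2))[:, None] * g[None, :]
    return dff + rng.normal(0, noise_sd, dff.shape)


class TestBaseline:
    def test_constant_kymograph(self):
        kymo = _kymo(np.full((64, 500), 120.0))
        f0, qc = caflux.estimate_baseline(kymo)
        assert np.allclose(f0, 120.0)
        assert qc == []

    def test_baseline_recovery_with_sparse_sparks(self):
        cfg = ScanSimConfig(pacing_hz=0.0, spark_rate_per_site_per_s=0.02,
                            duration_s=8.0)
        kymo, _ = make_linescan(cfg, 2)
        f0, _ = caflux.estimate_baseline(kymo)
        assert np.all(np.abs(f0 - cfg.f0_counts) / cfg.f0_counts < 0.05)

    def test_zero_column_floored_with_flag(self):
        pix = np.full((64, 500), 100.0)
        pix[10, :] = 0.0
        f0, qc = caflux.estimate_baseline(_kymo(pix))
        assert np.all(f0 >= 1.0)
        assert "baseline_floored" in qc

    def test_too_few_lines_raises(self):
        with pytest.raises(ValueError, match="100"):
            caflux.estimate_baseline(_kymo(np.full((64, 80), 100.0)))


class TestNormalize:
    def test_identities_and_elementwise_oracle(self, rng):
        kymo = _kymo(np.full((32, 200), 50.0))
        f0 = np.full(32, 50.0)
        assert np.allclose(caflux.normalize_dff(kymo, f0), 0.0)
        kymo2 = _kymo(np.full((32, 200), 100.0))
        assert np.allclose(caflux.normalize_dff(kymo2, f0), 1.0)
        pix = rng.uniform(10, 200, (32, 200))
        got = caflux.normalize_dff(_kymo(pix), f0)
        assert np.allclose(got, (pix - 50.0) / 50.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="spatial"):
            caflux.normalize_dff(_kymo(np.full((32, 200), 50.0)), np.ones(16))


class TestSparkDetector:
    def test_constant_field_yields_no_events(self):
        events = caflux.detect_sparks(np.zeros((100, 500)), PX, DT)
        assert events == []

    def test_single_spark_recovered_within_tolerance(self, rng):
        dff = _spark_field(rng, amp=1.0, noise_sd=0.1)
        events = caflux.detect_sparks(dff, PX, DT)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_dff == pytest.approx(1.0, rel=0.15)
        assert ev.position_um == pytest.approx(10.0, abs=0.5)
        assert ev.fwhm_um == pytest.approx(2.0, rel=0.35)
        assert ev.duration_ms > 0

    def test_spark_in_exclusion_window_not_reported(self, rng):
        # spark peaking 50 ms after a stimulus is evoked, not spontaneous
        dff = _spark_field(rng, t0_s=1.05, noise_sd=0.05)
        events = caflux.detect_sparks(dff, PX, DT, pacing_times_s=[1.0])
        assert all(abs(e.time_s - 1.05) > 0.1 for e in events)
        assert caflux.detect_sparks(dff, PX, DT) != []  # visible without pacing

    def test_detection_monotone_in_amplitude(self):
        rates = []
        for amp in (0.2, 0.5, 1.0):
            det = 0
            for seed in range(15):
                rng = np.random.default_rng(seed)
                dff = _spark_field(rng, n_space=120, n_time=400, amp=amp,
                                   t0_s=0.6, noise_sd=0.1)
                det += bool(caflux.detect_sparks(dff, PX, DT))
            rates.append(det / 15)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0

    def test_null_false_positive_rate(self):
        fp, area = 0, 0.0
        for seed in range(10):
            cfg = ScanSimConfig(pacing_hz=0.0, duration_s=8.0)
            kymo, _ = make_linescan(cfg, seed)
            f0, _ = caflux.estimate_baseline(kymo)
            dff = caflux.normalize_dff(kymo, f0)
            fp += len(caflux.detect_sparks(dff, kymo.pixel_size_um,
                                           kymo.line_interval_ms))
            area += kymo.scan_length_um / 100.0 * kymo.duration_s
        assert fp / area <= 1.0


class TestSparkFrequency:
    def test_arithmetic(self):
        ev = [caflux.SparkEvent(0, 0, 1, 1, 1)] * 5
        assert caflux.spark_frequency(ev, 50.0, 10.0) == pytest.approx(1.0)
        assert caflux.spark_frequency([], 50.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            caflux.spark_frequency(ev, 50.0, 0.0)

    def test_estimate_within_poisson_ci(self):
        inside = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = ScanSimConfig(pacing_hz=0.0, spark_rate_per_site_per_s=0.1,
                                duration_s=15.0)
            kymo, truth = make_linescan(cfg, seed)
            f0, _ = caflux.estimate_baseline(kymo)
            dff = caflux.normalize_dff(kymo, f0)
            n = len(caflux.detect_sparks(dff, kymo.pixel_size_um,
                                         kymo.line_interval_ms))
            lam = 0.1 * len(truth.site_positions_um) * cfg.duration_s
            lo, hi = stats.poisson.ppf([0.025, 0.975], lam)
            inside += lo <= n <= hi
        assert inside >= n_seeds - 2


class TestTransients:
    def test_amplitude_matches_generated(self, paced_scan):
        cfg, kymo, _truth = paced_scan
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        recs = caflux.detect_transients(dff, kymo.pacing_times_s,
                                        kymo.line_interval_ms)
        assert len(recs) == len(kymo.pacing_times_s)
        for r in recs:
            assert r.amplitude_dff == pytest.approx(cfg.transient_amplitude_dff,
                                                    rel=0.05)

    def test_no_stimuli_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            caflux.detect_transients(np.zeros((10, 100)), [], DT)

    def test_overlapping_windows_raise(self):
        with pytest.raises(ValueError, match="window"):
            caflux.detect_transients(np.zeros((10, 1000)), [0.1, 0.2, 0.3], DT)

    def test_zero_field_gives_zero_amplitudes(self):
        recs = caflux.detect_transients(np.zeros((10, 1000)), [0.5, 1.5], DT)
        assert all(r.amplitude_dff == 0.0 for r in recs)


class TestDyadCoupling:
    def test_full_coupling_zero_missed(self, paced_scan):
        _cfg, kymo, truth = paced_scan
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        res = caflux.score_dyad_coupling(dff, kymo.pacing_times_s,
                                         kymo.pixel_size_um, kymo.line_interval_ms)
        assert res.missed_rate_per_100um == 0.0
        assert res.inconsistent_sites == []
        assert res.activation_matrix.all()
        assert len(res.site_positions_um) == len(truth.site_positions_um)

    def test_partial_coupling_recovers_miss_fraction(self):
        cfg = ScanSimConfig(duration_s=16.0, p_couple=0.7)
        kymo, truth = make_linescan(cfg, 5)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        res = caflux.score_dyad_coupling(dff, kymo.pacing_times_s,
                                         kymo.pixel_size_um, kymo.line_interval_ms,
                                         site_positions_um=truth.site_positions_um)
        n_pairs = res.activation_matrix.size
        miss = (~res.activation_matrix).mean()
        se = np.sqrt(0.3 * 0.7 / n_pairs)
        assert abs(miss - 0.3) < 3 * se
        # activation calls agree with the generator's Bernoulli draws
        assert (res.activation_matrix == truth.activation_matrix).all()

    def test_silent_site_missed_but_not_inconsistent(self):
        # wide spacing so the activation window cannot see a neighbour's
        # release territory; the midpoint "site" then never releases
        cfg = ScanSimConfig(duration_s=6.0, dyad_spacing_um=4.0)
        kymo, truth = make_linescan(cfg, 1)
        f0, _ = caflux.estimate_baseline(kymo)
        dff = caflux.normalize_dff(kymo, f0)
        sites = list(truth.site_positions_um) + [4.0]
        res = caflux.score_dyad_coupling(dff, kymo.pacing_times_s,
                                         kymo.pixel_size_um, kymo.line_interval_ms,
                                         site_positions_um=sorted(sites))
        silent = sorted(sites).index(4.0)
        assert not res.activation_matrix[silent].any()
        assert silent not in res.inconsistent_sites
        assert res.missed_rate_per_100um > 0.0

    def test_too_few_stimuli_raise(self):
        with pytest.raises(ValueError, match="3 pacing"):
            caflux.score_dyad_coupling(np.zeros((10, 500)), [0.5, 1.5], PX, DT)


class TestSrContent:
    def test_no_caffeine_response_gives_near_zero_delta(self):
        cfg = ScanSimConfig(caffeine_mode=True, caffeine_depletion_frac=0.0,
                            duration_s=10.0)
        kymo, _ = make_linescan(cfg, 0)
        est = caflux.sr_content_caffeine(kymo)
        assert est.delta_over_f0 < 0.02

    def test_store_scale_ratio_recovered(self):
        ratios = []
        for seed in range(6):
            k1, _ = make_linescan(ScanSimConfig(caffeine_mode=True,
                                                duration_s=12.0,
                                                store_scale=1.0), seed)
            k2, _ = make_linescan(ScanSimConfig(caffeine_mode=True,
                                                duration_s=12.0,
                                                store_scale=0.75), seed + 100)
            ratios.append(caflux.sr_content_caffeine(k2).delta_over_f0 /
                          caflux.sr_content_caffeine(k1).delta_over_f0)
        assert np.mean(ratios) == pytest.approx(0.75, abs=0.05)

    def test_missing_caffeine_time_raises(self):
        kymo = _kymo(np.full((64, 1000), 100.0))
        with pytest.raises(ValueError, match="caffeine"):
            caflux.sr_content_caffeine(kymo)

    def test_zero_baseline_raises(self):
        kymo = _kymo(np.zeros((64, 2000)))
        kymo.caffeine_time_s = 3.0
        with pytest.raises(ValueError, match="baseline"):
            caflux.sr_content_caffeine(kymo)
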