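import dataclasses

import numpy as np
import pytest

from tenomech.curves import (
    AnalysisThresholds,
    LinearRegionError,
    analyze_record,
    compute_stiffness,
    detect_failures,
    detect_linear_region,
    infer_failure_mode,
    strip_preconditioning,
    ultimate_load,
)
from tenomech.io import TensileRecord, ValidationError
from tenomech.simulate import CurveParams, simulate_curve
from tenomech.validation import failure_scan_bruteforce, linear_region_bruteforce


def make_ramp(d, f, preload=2.0):
    d = np.asarray(d, dtype=float)
    return TensileRecord("ramp", d / (100 / 60), d, np.asarray(f, dtype=float),
                         preload=preload)


class TestStripPreconditioning:
    def test_stripped_equals_curve_without_cycles(self):
        base = CurveParams(k_true=40.0, ultimate_load_true=100.0, noise_sd=0.0, seed=2)
        with_pre, _ = simulate_curve(base)
        without, _ = simulate_curve(dataclasses.replace(base, precondition_cycles=0))
        stripped = strip_preconditioning(with_pre, 5)
        assert np.all(np.diff(stripped.displacement_mm) > 0)
        np.testing.assert_allclose(stripped.displacement_mm, without.displacement_mm, atol=1e-12)
        np.testing.assert_allclose(stripped.force_n, without.force_n, atol=1e-12)
        np.testing.assert_allclose(stripped.time_s, without.time_s, atol=1e-9)

    def test_record_without_cycles_returned_unchanged(self, caplog):
        rec, _ = simulate_curve(CurveParams(precondition_cycles=0, noise_sd=0.0, seed=3))
        with caplog.at_level("WARNING"):
            out = strip_preconditioning(rec, 5)
        assert out is rec
        assert "reversals" in caplog.text

    def test_idempotent_on_stripped_ramp(self, noisy_curve):
        rec, _ = noisy_curve
        once = strip_preconditioning(rec, 5)
        twice = strip_preconditioning(once, 5)
        np.testing.assert_array_equal(once.force_n, twice.force_n)
        np.testing.assert_array_equal(once.displacement_mm, twice.displacement_mm)

    def test_cycles_without_ramp_is_error(self):
        rec, _ = simulate_curve(CurveParams(noise_sd=0.0, seed=4))
        sign = np.sign(np.diff(rec.displacement_mm))
        sign[sign == 0] = 1
        flips = np.nonzero(sign[1:] != sign[:-1])[0] + 1
        cut = int(flips[9]) + 3  # keep all 10 reversals, only 3 ramp samples
        head = rec.with_samples(rec.time_s[:cut], rec.displacement_mm[:cut], rec.force_n[:cut])
        with pytest.raises(ValidationError, match="ramp"):
            strip_preconditioning(head, 5)


class TestLinearRegion:
    def test_perfect_line_selects_full_range(self):
        d = np.linspace(0.0, 5.0, 251)
        rec = make_ramp(d, 2.0 + 50.0 * d)
        i, j, slope, r2 = detect_linear_region(rec, r2_min=0.99)
        assert (i, j) == (0, 250)
        assert slope == pytest.approx(50.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_toe_curve_matches_bruteforce_enumeration(self):
        rec, _ = simulate_curve(CurveParams(k_true=40.0, toe_length=1.0, toe_exponent=2.0,
                                            ultimate_load_true=60.0, noise_sd=0.0,
                                            precondition_cycles=0, step=0.02, seed=5))
        fast = detect_linear_region(rec)
        slow = linear_region_bruteforce(rec)
        assert fast[:2] == slow[:2]
        assert fast[2] == pytest.approx(slow[2], rel=1e-9)
        # the toe (first mm) is largely excluded from the fitted window
        assert rec.displacement_mm[fast[0]] > 0.5

    def test_pure_noise_has_no_linear_region(self):
        rng = np.random.default_rng(6)
        d = np.arange(0.0, 3.0, 0.01)
        rec = make_ramp(d, 10.0 + rng.normal(0, 1.0, d.size))
        with pytest.raises(LinearRegionError):
            detect_linear_region(rec)
        with pytest.raises(LinearRegionError):
            linear_region_bruteforce(rec)

    def test_region_confined_before_end_index(self):
        d = np.linspace(0.0, 4.0, 201)
        f = 2.0 + 30.0 * d
        f[150:] = f[149]  # plateau after sample 150
        rec = make_ramp(d, f)
        i, j, slope, _ = detect_linear_region(rec, end_index=150)
        assert j <= 149
        assert slope == pytest.approx(30.0, abs=1e-9)


class TestStiffness:
    def test_exact_line(self):
        d = np.linspace(0, 2, 100)
        rec = make_ramp(d, 10.0 * d)
        assert compute_stiffness(rec, (0, 99)) == pytest.approx(10.0, abs=1e-12)

    def test_noisy_line_within_ols_tolerance(self):
        rng = np.random.default_rng(7)
        d = np.linspace(0, 5, 500)
        rec = make_ramp(d, 10.0 * d + rng.normal(0, 0.1, 500))
        assert compute_stiffness(rec, (0, 499)) == pytest.approx(10.0, abs=0.1)

    def test_two_sample_region_rejected(self):
        d = np.linspace(0, 1, 50)
        rec = make_ramp(d, 10 * d)
        with pytest.raises(ValidationError):
            compute_stiffness(rec, (0, 1))


class TestDetectFailures:
    def test_monotone_ramp_single_event(self):
        d = np.arange(0.0, 2.0, 0.01)
        f = np.concatenate([2.0 + 49.0 * d[:-20], np.full(20, 1.0)])
        rec = make_ramp(d, f)
        events = detect_failures(rec)
        assert len(events) == 1
        assert events[0][1] == f.max()

    def test_partial_failure_yields_two_ordered_events(self):
        rec, truth = simulate_curve(CurveParams(
            k_true=50.0, ultimate_load_true=120.0, toe_length=0.0,
            partial_failures=((1.5, 0.1),), noise_sd=0.0, precondition_cycles=0, seed=8))
        events = detect_failures(rec, min_drop_frac=0.05)
        assert len(events) == 2
        assert events[0][1] < events[1][1]
        assert events[0][1] == pytest.approx(truth.true_first_failure_load, abs=1e-9)

    def test_noise_jitter_not_promoted_to_failures(self):
        rec, _ = simulate_curve(CurveParams(k_true=40.0, ultimate_load_true=150.0,
                                            noise_sd=0.5, precondition_cycles=0, seed=9))
        events = detect_failures(rec)
        assert len(events) == 1
        assert events[0][1] == rec.force_n.max()

    def test_matches_bruteforce_scan(self, noisy_curve):
        rec, _ = noisy_curve
        ramp = strip_preconditioning(rec, 5)
        assert detect_failures(ramp) == failure_scan_bruteforce(ramp)

    def test_too_few_samples_rejected(self):
        rec = make_ramp([0.0, 0.1], [2.0, 3.0])
        with pytest.raises(ValidationError):
            detect_failures(rec)


class TestUltimateLoad:
    def test_equals_sample_maximum_exactly(self, noisy_curve):
        rec, _ = noisy_curve
        load, _ = ultimate_load(rec)
        assert load == rec.force_n.max()

    def test_tie_breaks_to_earliest(self):
        rec = make_ramp([0, 0.1, 0.2, 0.3], [5.0, 5.0, 5.0, 5.0])
        load, disp = ultimate_load(rec)
        assert (load, disp) == (5.0, 0.0)


class TestFailureMode:
    @pytest.mark.parametrize("mode", ["pullout", "breakage"])
    def test_recovers_simulated_mode(self, mode):
        rec, _ = simulate_curve(CurveParams(post_mode=mode, noise_sd=0.0,
                                            precondition_cycles=0, seed=10))
        assert infer_failure_mode(rec) == mode

    def test_truncated_at_peak_undetermined(self, plain_curve):
        rec, _ = plain_curve
        peak = int(np.argmax(rec.force_n))
        head = rec.with_samples(rec.time_s[:peak + 1], rec.displacement_mm[:peak + 1],
                                rec.force_n[:peak + 1])
        assert infer_failure_mode(head) == "undetermined"


class TestAnalyzeRecord:
    def test_noise_free_full_chain(self, toe_curve):
        rec, truth = toe_curve
        feats = analyze_record(rec)
        assert feats.ultimate_load == pytest.approx(100.0, abs=1e-9)
        assert feats.first_failure_load == feats.ultimate_load
        assert feats.n_partial_failures == 0
        assert feats.failure_mode == "pullout"

    def test_first_failure_never_exceeds_ultimate(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            params = CurveParams(
                k_true=float(rng.uniform(20, 80)),
                ultimate_load_true=float(rng.uniform(80, 300)),
                noise_sd=0.5, seed=int(rng.integers(2**31)))
            rec, _ = simulate_curve(params)
            feats = analyze_record(rec)
            assert feats.first_failure_load <= feats.ultimate_load

    def test_failed_region_search_reported_as_nan(self, caplog):
        rng = np.random.default_rng(12)
        d = np.arange(0.0, 3.0, 0.01)
        f = 10.0 + rng.normal(0, 1.0, d.size)
        f[-1] = 30.0  # a clear ultimate spike
        rec = make_ramp(d, f)
        with caplog.at_level("WARNING"):
            feats = analyze_record(rec, stripped=True)
        assert np.isnan(feats.stiffness)
        assert feats.ultimate_load == 30.0
        assert "excluded" in caplog.text
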