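import dataclasses

import numpy as np
import pytest

from conftest import count_strict_local_maxima
from tenomech.io import ValidationError
from tenomech.simulate import (
    CohortParams,
    CurveParams,
    GroupParams,
    simulate_curve,
    simulate_experiment,
)


class TestSimulateCurve:
    def test_noise_free_maximum_equals_ultimate(self, plain_curve):
        rec, truth = plain_curve
        assert abs(rec.force_n.max() - truth.true_ultimate_load) < 1e-9

    def test_noise_free_prepeak_slope_is_exact(self, plain_curve):
        rec, _ = plain_curve
        peak = int(np.argmax(rec.force_n))
        slopes = np.diff(rec.force_n[:peak + 1]) / np.diff(rec.displacement_mm[:peak + 1])
        np.testing.assert_allclose(slopes, 50.0, rtol=1e-9)

    def test_toe_region_is_c1_into_linear_part(self, toe_curve):
        rec, truth = toe_curve
        d, f = rec.displacement_mm, rec.force_n
        k, L, e, P = 40.0, 1.0, 2.0, 2.0
        at_toe_end = P + k * L / e
        idx = np.nonzero(np.isclose(d, L) & (f > P))[0]
        assert idx.size and abs(f[idx[-1]] - at_toe_end) < 1e-9

    def test_partial_failure_gives_two_local_maxima(self):
        params = CurveParams(k_true=50.0, ultimate_load_true=100.0, toe_length=0.0,
                             partial_failures=((1.2, 0.1),), noise_sd=0.0,
                             precondition_cycles=0, seed=4)
        rec, truth = simulate_curve(params)
        assert count_strict_local_maxima(rec.force_n) == 2
        assert truth.true_first_failure_load == pytest.approx(2.0 + 50 * 1.2)
        assert truth.true_first_failure_load < truth.true_ultimate_load

    def test_same_seed_bit_identical(self):
        p = CurveParams(noise_sd=0.5, seed=42)
        r1, _ = simulate_curve(p)
        r2, _ = simulate_curve(p)
        assert np.array_equal(r1.force_n, r2.force_n)
        assert np.array_equal(r1.time_s, r2.time_s)

    def test_partial_failure_beyond_ultimate_rejected(self):
        params = CurveParams(k_true=50.0, ultimate_load_true=60.0, toe_length=0.0,
                             partial_failures=((5.0, 0.1),), precondition_cycles=0)
        with pytest.raises(ValidationError, match="ultimate"):
            simulate_curve(params)

    @pytest.mark.parametrize("bad", [
        dict(k_true=-1.0),
        dict(ultimate_load_true=1.0),          # below preload
        dict(partial_failures=((2.0, 1.2),)),  # drop fraction outside (0,1)
        dict(noise_sd=-0.1),
        dict(post_mode="melt"),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValidationError):
            simulate_curve(CurveParams(**bad))

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_no_sample_exceeds_ultimate_plus_noise_band(self, seed):
        p = CurveParams(k_true=30.0, ultimate_load_true=120.0, noise_sd=0.5, seed=seed)
        rec, truth = simulate_curve(p)
        assert rec.force_n.max() <= truth.true_ultimate_load + 4 * p.noise_sd

    def test_preconditioning_produces_expected_reversals(self, toe_curve):
        rec, _ = toe_curve
        sign = np.sign(np.diff(rec.displacement_mm))
        sign[sign == 0] = 1
        reversals = int(np.sum(sign[1:] != sign[:-1]))
        assert reversals == 2 * 5

    def test_breakage_collapses_within_one_sample(self):
        p = CurveParams(post_mode="breakage", noise_sd=0.0, precondition_cycles=0, seed=6)
        rec, _ = simulate_curve(p)
        peak = int(np.argmax(rec.force_n))
        assert rec.force_n[peak + 1] <= p.preload


class TestSimulateExperiment:
    def test_cohort_counts_and_joinable_ids(self):
        records, geoms, truths = simulate_experiment(CohortParams(seed=1))
        assert len(records) == len(geoms) == len(truths) == 36
        ids = {r.specimen_id for r in records}
        assert ids == {g.specimen_id for g in geoms} == {t.specimen_id for t in truths}

    def test_zero_sd_groups_are_degenerate(self):
        groups = {"A": GroupParams(n=3, stiffness_sd=0.0, ultimate_sd=0.0),
                  "B": GroupParams(n=3, stiffness_sd=0.0, ultimate_sd=0.0)}
        _, _, truths = simulate_experiment(CohortParams(groups=groups, seed=2))
        by_group = {}
        for t in truths:
            by_group.setdefault(t.specimen_id.split("-")[0], []).append(t.true_stiffness)
        for vals in by_group.values():
            assert len(set(vals)) == 1

    def test_configured_ordering_preserved_in_sample_means(self):
        # WF > FR > PT in truth with tight SDs: the sample means must keep
        # the ordering for every seed in a sweep (separation >> SD/sqrt(n))
        groups = {
            "PT": GroupParams(n=12, stiffness_mean=25.0, stiffness_sd=2.0),
            "FR": GroupParams(n=12, stiffness_mean=35.0, stiffness_sd=2.0),
            "WF": GroupParams(n=12, stiffness_mean=45.0, stiffness_sd=2.0),
        }
        for seed in range(10):
            _, _, truths = simulate_experiment(CohortParams(groups=groups, seed=seed))
            means = {}
            for t in truths:
                means.setdefault(t.specimen_id.split("-")[0], []).append(t.true_stiffness)
            m = {g: np.mean(v) for g, v in means.items()}
            assert m["WF"] > m["FR"] > m["PT"]

    def test_geometry_matches_drawn_bulk_ratio(self):
        from tenomech.geometry import bulk_result

        _, geoms, _ = simulate_experiment(CohortParams(seed=3))
        for g in geoms:
            br = bulk_result(g).bulk_ratio
            assert 10.0 < br < 200.0

    def test_experiment_deterministic(self):
        c = CohortParams(seed=7)
        r1, g1, t1 = simulate_experiment(c)
        r2, g2, t2 = simulate_experiment(c)
        assert g1 == g2
        for a, b in zip(r1, r2):
            assert np.array_equal(a.force_n, b.force_n)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValidationError):
            CohortParams(groups={"A": GroupParams(n=1), "B": GroupParams(n=3)}).validate()
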