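"""Synthetic load-deformation curves and whole experiments with known truth.

The noise-free force model is piecewise and analytically tractable so that
every derived quantity (linear-region slope, local maxima, global maximum)
is known in closed form:

* toe region, 0 <= d <= L:   F(d) = P + k * d**e / (e * L**(e-1))
* linear region, d > L:      F(d) = P + k * (d - L*(1 - 1/e))

which is C1-continuous at d = L with slope exactly k in the linear part.
Partial failures drop the force above preload by a fraction and resume at
slope k; the global maximum equals the configured ultimate load; afterwards
a pull-out decays linearly while a breakage collapses to a residual below
preload within one sample. Gaussian machine noise is added to force, and
optional preconditioning cycles are prepended as triangular displacement
waves. Sampling is uniform in displacement (velocity is metadata only).

Randomness uses numpy's PCG64 via ``numpy.random.default_rng(seed)``; the
generator is part of the public contract so identical seeds give
bit-identical records across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from tenomech.io import SpecimenGeometry, TensileRecord, ValidationError

__all__ = [
    "CohortParams",
    "CurveParams",
    "GroupParams",
    "SimulationTruth",
    "simulate_curve",
    "simulate_experiment",
    "truths_to_frame",
]


@dataclass(frozen=True)
class CurveParams:
    """Generating parameters of one synthetic tensile test.

    Protocol defaults follow the emulated experiment: 2 N preload, 5
    preconditioning cycles with amplitude 5% of the clamp distance at
    10 mm/min, failure ramp at 100 mm/min. The default clamp distance is
    chosen so the preconditioning wave stays within the toe region, as in
    real protocols where preconditioning loads are a small fraction of the
    failure load.
    """

    k_true: float = 40.0                 # N/mm, linear-region stiffness
    toe_length: float = 1.0              # mm of toe-region displacement
    toe_exponent: float = 2.0            # dimensionless, >= 1
    partial_failures: tuple[tuple[float, float], ...] = ()  # (displacement mm, drop fraction)
    ultimate_load_true: float = 100.0    # N, global maximum force
    post_mode: str = "pullout"           # {"pullout", "breakage"}
    pullout_decay: float = 25.0          # N/mm decline after the peak
    noise_sd: float = 0.5                # N, Gaussian machine noise
    preload: float = 2.0                 # N
    precondition_cycles: int = 5
    precondition_amplitude: float = 0.05  # fraction of clamp distance
    ramp_velocity: float = 100.0         # mm/min
    precondition_velocity: float = 10.0  # mm/min
    clamp_distance: float = 20.0         # mm
    step: float = 0.01                   # mm displacement sampling step
    seed: int = 0

    def validate(self) -> "CurveParams":
        if not self.k_true > 0:
            raise ValidationError("k_true must be > 0")
        if not self.ultimate_load_true > self.preload:
            raise ValidationError("ultimate_load_true must exceed preload")
        if self.toe_length < 0 or self.toe_exponent < 1:
            raise ValidationError("toe_length >= 0 and toe_exponent >= 1 required")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.post_mode not in ("pullout", "breakage"):
            raise ValidationError(f"unknown post_mode {self.post_mode!r}")
        if self.pullout_decay <= 0 or self.step <= 0:
            raise ValidationError("pullout_decay and step must be > 0")
        for d, fr in self.partial_failures:
            if not 0 < fr < 1:
                raise ValidationError("drop_fraction must lie in (0, 1)")
            if d <= self.toe_length:
                raise ValidationError("partial failures must lie beyond the toe region")
        return self


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one synthetic curve, for recovery tests."""

    specimen_id: str
    params: CurveParams
    true_stiffness: float
    true_first_failure_load: float
    true_ultimate_load: float
    true_linear_region: tuple[float, float]  # (mm, mm) of the failure ramp
    post_mode: str

    def __post_init__(self) -> None:
        if self.true_first_failure_load > self.true_ultimate_load + 1e-12:
            raise ValidationError("first failure truth exceeds ultimate truth")


def _segments(p: CurveParams) -> tuple[list[tuple[float, float]], float, list[float]]:
    """Linear-branch shifts after each partial failure.

    Returns (events, d_ult, shifts) where events is a list of
    (displacement, pre-drop peak force), shifts[i] is the x-intercept shift of
    the linear branch active after the i-th event (shifts[0] before any), and
    d_ult the displacement where the final branch reaches the ultimate load.
    """
    k, P, U = p.k_true, p.preload, p.ultimate_load_true
    shift0 = p.toe_length * (1.0 - 1.0 / p.toe_exponent) if p.toe_length > 0 else 0.0
    shifts = [shift0]
    events: list[tuple[float, float]] = []
    last_d = p.toe_length
    for d_i, fr in sorted(p.partial_failures):
        if d_i <= last_d:
            raise ValidationError("partial failure displacements must be increasing and beyond the toe")
        f_pre = P + k * (d_i - shifts[-1])
        if f_pre >= U:
            raise ValidationError(
                f"partial failure at {d_i} mm reaches {f_pre:.3f} N, not below the ultimate load {U} N")
        if f_pre <= P:
            raise ValidationError("partial failure occurs below preload")
        # post-drop force P + (1-fr)*(f_pre-P), same slope k
        shifts.append(d_i - (1.0 - fr) * (d_i - shifts[-1]))
        events.append((d_i, f_pre))
        last_d = d_i
    d_ult = shifts[-1] + (U - P) / k
    if events and d_ult <= events[-1][0]:
        raise ValidationError("ultimate load is reached before the last partial failure")
    return events, d_ult, shifts


def _force_noise_free(d: np.ndarray, p: CurveParams,
                      events: list[tuple[float, float]], d_ult: float,
                      shifts: list[float]) -> np.ndarray:
    """Evaluate the piecewise model on the loading ramp (d <= d_ult).

    At an event displacement exactly, the pre-drop (peak) value is returned.
    """
    k, P, L, e = p.k_true, p.preload, p.toe_length, p.toe_exponent
    f = np.empty_like(d)
    if L > 0:
        toe = d <= L
        f[toe] = P + k * d[toe] ** e / (e * L ** (e - 1.0))
    else:
        toe = np.zeros(d.shape, dtype=bool)
    bounds = [ev[0] for ev in events] + [np.inf]
    lo = L
    for shift, hi in zip(shifts, bounds):
        seg = (~toe) & (d > lo) & (d <= hi)
        f[seg] = P + k * (d[seg] - shift)
        lo = hi
    if L == 0:
        f[d == 0] = P
    return f


def _ramp_grid(p: CurveParams, events: list[tuple[float, float]], d_ult: float) -> np.ndarray:
    """Uniform displacement grid over [0, d_ult] with event displacements and
    the peak inserted exactly so analytic maxima appear in the samples."""
    g = np.arange(0.0, d_ult, p.step)
    specials = np.array([ev[0] for ev in events] + [d_ult])
    if g.size:
        # keep the exact special points; drop uniform points so close that the
        # time increment would round away
        far = np.all(np.abs(g[:, None] - specials[None, :]) > p.step * 1e-3, axis=1)
        g = g[far]
    return np.sort(np.concatenate([g, specials]))


def simulate_curve(params: CurveParams) -> tuple[TensileRecord, SimulationTruth]:
    """Generate one synthetic tensile record plus its ground truth.

    Deterministic given ``params.seed``. The noise-free sampled maximum
    equals ``ultimate_load_true`` exactly because the peak displacement is
    inserted into the sampling grid.
    """
    p = params.validate()
    events, d_ult, shifts = _segments(p)
    rng = np.random.default_rng(p.seed)

    ramp_d = _ramp_grid(p, events, d_ult)
    ramp_f = _force_noise_free(ramp_d, p, events, d_ult, shifts)

    # post-peak branch
    if p.post_mode == "pullout":
        extent = (p.ultimate_load_true - p.preload) / p.pullout_decay
        post_d = np.arange(p.step, extent + p.step / 2, p.step) + d_ult
        post_f = p.ultimate_load_true - p.pullout_decay * (post_d - d_ult)
        post_f = np.maximum(post_f, 0.0)
    else:  # breakage: collapse within one sample, short residual tail
        residual = min(p.preload / 4.0, 0.5)
        post_d = np.arange(p.step, 1.5 + p.step / 2, p.step) + d_ult
        post_f = np.full(post_d.shape, residual)

    d = np.concatenate([ramp_d, post_d])
    f = np.concatenate([ramp_f, post_f])

    if p.precondition_cycles > 0:
        amp = p.precondition_amplitude * p.clamp_distance
        n_up = max(2, int(round(amp / p.step)))
        up = np.linspace(amp / n_up, amp, n_up)
        down = up[::-1] - amp / n_up  # ends at exactly 0
        cycle = np.concatenate([up, down])
        pre_d = np.concatenate([np.zeros(1), np.tile(cycle, p.precondition_cycles)])
        # preconditioning loads follow the pre-failure branch of the model
        pre_f = _force_noise_free(np.abs(pre_d), p, [], d_ult, [shifts[0]])
        if pre_f.max() >= p.ultimate_load_true:
            raise ValidationError(
                "preconditioning amplitude drives the force beyond the ultimate load; "
                "reduce precondition_amplitude or clamp_distance")
        v_pre = p.precondition_velocity / 60.0  # mm/s
        pre_t = np.concatenate([np.zeros(1), np.cumsum(np.abs(np.diff(pre_d)) / v_pre)])
        v_ramp = p.ramp_velocity / 60.0
        # preconditioning ends at displacement 0, which doubles as the first
        # ramp sample; the ramp proper continues from d[1:]
        time = np.concatenate([pre_t, pre_t[-1] + d[1:] / v_ramp])
        displacement = np.concatenate([pre_d, d[1:]])
        force = np.concatenate([pre_f, f[1:]])
    else:
        v_ramp = p.ramp_velocity / 60.0
        time = d / v_ramp
        displacement = d
        force = f

    if p.noise_sd > 0:
        force = force + rng.normal(0.0, p.noise_sd, force.size)

    record = TensileRecord(
        specimen_id=f"sim-{p.seed}",
        time_s=time, displacement_mm=displacement, force_n=force,
        preload=p.preload, ramp_velocity=p.ramp_velocity,
    ).validate()

    first_fail = events[0][1] if events else p.ultimate_load_true
    d_first_event = events[0][0] if events else d_ult
    truth = SimulationTruth(
        specimen_id=record.specimen_id, params=p,
        true_stiffness=p.k_true,
        true_first_failure_load=first_fail,
        true_ultimate_load=p.ultimate_load_true,
        true_linear_region=(p.toe_length, d_first_event),
        post_mode=p.post_mode,
    )
    return record, truth


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass(frozen=True)
class GroupParams:
    """Between-specimen distribution of one technique group.

    Truths are drawn from normals truncated at 3 SD and at physical lower
    bounds (stiffness and loads strictly positive and above preload) so no
    draw is unphysical. Donor tendons are given a slightly smaller caliber
    than recipients, matching the anatomy that motivates the donor/recipient
    role split.
    """

    n: int = 12
    stiffness_mean: float = 40.0       # N/mm
    stiffness_sd: float = 6.0
    ultimate_mean: float = 150.0       # N
    ultimate_sd: float = 25.0
    bulk_ratio_mean: float = 125.0     # %
    bulk_ratio_sd: float = 12.0
    native_diameter_mean: float = 4.0  # mm
    native_diameter_sd: float = 0.3
    overlap_mean: float = 30.0         # mm
    overlap_sd: float = 1.0
    post_mode: str = "pullout"

    def validate(self) -> "GroupParams":
        if self.n < 2:
            raise ValidationError("each group needs n >= 2")
        for name in ("stiffness_sd", "ultimate_sd", "bulk_ratio_sd",
                     "native_diameter_sd", "overlap_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        return self


@dataclass(frozen=True)
class CohortParams:
    """A whole experiment: one GroupParams per technique plus shared protocol."""

    groups: dict[str, GroupParams] = field(default_factory=lambda: {
        "PT": GroupParams(stiffness_mean=25.0, ultimate_mean=110.0, bulk_ratio_mean=140.0),
        "FR": GroupParams(stiffness_mean=35.0, ultimate_mean=150.0, bulk_ratio_mean=125.0),
        "WF": GroupParams(stiffness_mean=45.0, ultimate_mean=190.0, bulk_ratio_mean=105.0),
    })
    protocol: CurveParams = CurveParams()
    seed: int = 0

    def validate(self) -> "CohortParams":
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups")
        for g in self.groups.values():
            g.validate()
        return self


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float) -> float:
    """Normal draw truncated at 3 SD and at a physical lower bound."""
    if sd == 0:
        if mean <= lower:
            raise ValidationError(f"degenerate draw {mean} at or below bound {lower}")
        return mean
    lo, hi = max(lower, mean - 3 * sd), mean + 3 * sd
    if hi <= lo:
        raise ValidationError(f"truncation interval empty for mean={mean}, sd={sd}, lower={lower}")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return x
    raise ValidationError("truncated-normal rejection sampling failed")  # pragma: no cover


def simulate_experiment(
    cohort: CohortParams,
) -> tuple[list[TensileRecord], list[SpecimenGeometry], list[SimulationTruth]]:
    """Simulate every specimen of a cohort; tables join on specimen_id.

    Per-specimen curve parameters are drawn from the group distributions;
    repair-zone diameters are set so each specimen's true bulk ratio equals
    its drawn value exactly (elliptical area model).
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    records: list[TensileRecord] = []
    geometries: list[SpecimenGeometry] = []
    truths: list[SimulationTruth] = []
    for label, gp in cohort.groups.items():
        for i in range(gp.n):
            sid = f"{label}-{i + 1:02d}"
            k = _trunc_normal(rng, gp.stiffness_mean, gp.stiffness_sd, 1.0)
            ult = _trunc_normal(rng, gp.ultimate_mean, gp.ultimate_sd,
                                cohort.protocol.preload + 5.0)
            seed_i = int(rng.integers(0, 2**31 - 1))
            params = replace(cohort.protocol, k_true=k, ultimate_load_true=ult,
                             post_mode=gp.post_mode, seed=seed_i)
            rec, truth = simulate_curve(params)
            rec = replace(rec, specimen_id=sid)
            truth = replace(truth, specimen_id=sid)

            dd1 = _trunc_normal(rng, 0.9 * gp.native_diameter_mean, gp.native_diameter_sd, 0.5)
            dd2 = _trunc_normal(rng, 0.9 * gp.native_diameter_mean, gp.native_diameter_sd, 0.5)
            dr1 = _trunc_normal(rng, 1.1 * gp.native_diameter_mean, gp.native_diameter_sd, 0.5)
            dr2 = _trunc_normal(rng, 1.1 * gp.native_diameter_mean, gp.native_diameter_sd, 0.5)
            br = _trunc_normal(rng, gp.bulk_ratio_mean, gp.bulk_ratio_sd, 10.0)
            area_native = np.pi * dd1 * dd2 / 4.0 + np.pi * dr1 * dr2 / 4.0
            area_repair = br / 100.0 * area_native
            d_rep = float(np.sqrt(4.0 * area_repair / np.pi))
            overlap = _trunc_normal(rng, gp.overlap_mean, gp.overlap_sd, 5.0)
            geometries.append(SpecimenGeometry(
                specimen_id=sid, technique=label,
                d_donor_1=dd1, d_donor_2=dd2, d_recip_1=dr1, d_recip_2=dr2,
                d_repair_1=d_rep, d_repair_2=d_rep, overlap=overlap,
            ))
            records.append(rec)
            truths.append(truth)
    return records, geometries, truths


def truths_to_frame(truths: Sequence[SimulationTruth]):
    """Tabulate ground truths for joining with analysis output."""
    import pandas as pd

    return pd.DataFrame([{
        "specimen_id": t.specimen_id,
        "true_stiffness": t.true_stiffness,
        "true_first_failure_load": t.true_first_failure_load,
        "true_ultimate_load": t.true_ultimate_load,
        "true_linear_start": t.true_linear_region[0],
        "true_linear_end": t.true_linear_region[1],
        "post_mode": t.post_mode,
        "seed": t.params.seed,
    } for t in truths])
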