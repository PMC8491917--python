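"""From raw tensile records to curve features.

The analysis chain: strip preconditioning cycles, detect failure events
(local maxima followed by a qualifying force drop), locate the linear
elastic region before the first failure by coefficient of determination,
compute stiffness as the OLS slope on that region, read the ultimate load
off the global maximum, and classify the failure mode from the post-peak
shape.

Detection steps (displacement reversals, extrema, post-peak cliffs) run on a
lightly smoothed trace (centered moving average, default width 5 samples)
because thresholds on raw noisy differences are fragile; every *reported*
load is read from the raw, unfiltered samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from tenomech.io import TensileRecord, ValidationError, get_logger

__all__ = [
    "AnalysisThresholds",
    "CurveFeatures",
    "LinearRegionError",
    "analyze_record",
    "compute_stiffness",
    "detect_failures",
    "detect_linear_region",
    "infer_failure_mode",
    "strip_preconditioning",
    "ultimate_load",
]


class LinearRegionError(ValueError):
    """No window meets the R-squared criterion; specimen excluded from
    stiffness statistics (but retained for load statistics)."""


@dataclass(frozen=True)
class AnalysisThresholds:
    """Tunable thresholds of the curve analysis.

    r2_min / min_span_frac define the linear elastic region: the longest
    contiguous window spanning at least ``min_span_frac`` of the pre-failure
    displacement range whose OLS fit reaches R^2 >= ``r2_min``.
    ``min_drop_frac`` is the force drop (as a fraction of the running
    maximum above preload) that qualifies a local maximum as a failure
    event. ``cliff_frac``/``cliff_window`` drive the failure-mode heuristic:
    a fall below ``cliff_frac`` of the ultimate load within ``cliff_window``
    mm of the peak reads as suture breakage, a gradual decline as pull-out.
    """

    r2_min: float = 0.999
    min_span_frac: float = 0.2
    min_drop_frac: float = 0.05
    min_drop_abs: float = 2.0   # N, noise floor for failure events
    cliff_frac: float = 0.5
    cliff_window: float = 1.0   # mm
    smooth_window: int = 5      # samples, detection only
    n_precondition_cycles: int = 5

    def validate(self) -> "AnalysisThresholds":
        for name in ("r2_min", "min_span_frac", "min_drop_frac", "cliff_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.min_drop_abs < 0:
            raise ValidationError("min_drop_abs must be >= 0")
        if self.cliff_window <= 0 or self.smooth_window < 1:
            raise ValidationError("cliff_window > 0 and smooth_window >= 1 required")
        return self


@dataclass
class CurveFeatures:
    """Derived metrics of one specimen's load-deformation curve.

    ``stiffness`` is NaN when no linear region met the R^2 criterion; such
    specimens stay in the load statistics but are excluded from stiffness
    statistics.
    """

    specimen_id: str
    stiffness: float               # N/mm
    r2_linear: float
    linear_region: tuple[float, float]  # (start mm, end mm)
    first_failure_load: float      # N
    first_failure_displacement: float
    ultimate_load: float           # N
    ultimate_displacement: float
    failure_mode: str              # {pullout, breakage, undetermined}
    n_partial_failures: int


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage; identity for window 1."""
    if window <= 1 or x.size < window:
        return x
    kernel = np.ones(window) / window
    out = np.convolve(x, kernel, mode="same")
    # fix the shrinking-window edges explicitly
    half = window // 2
    for i in range(half):
        out[i] = x[: i + half + 1].mean()
        out[-(i + 1)] = x[-(i + half + 1):].mean()
    return out


def strip_preconditioning(record: TensileRecord, n_cycles: int = 5,
                          smooth_window: int = 5, min_ramp_samples: int = 10) -> TensileRecord:
    """Remove preconditioning load-unload cycles, keep the failure ramp.

    Displacement reversals are sign changes of the smoothed displacement
    increment; ``n_cycles`` triangular cycles produce ``2 * n_cycles``
    reversals (a peak and a trough each). The returned ramp is re-zeroed so
    displacement 0 sits at the preload crossing. If fewer reversals than
    expected are found the record is returned unchanged with a warning
    (which also makes the operation idempotent on already-stripped ramps);
    a record that reverses but never ramps to failure raises
    :class:`ValidationError`.
    """
    logger = get_logger()
    if n_cycles == 0:
        return record
    d = record.displacement_mm
    sm = _smooth(d, smooth_window)
    inc = np.diff(sm)
    sign = np.sign(inc)
    sign[sign == 0] = 1  # flats read as continuing motion
    flips = np.nonzero(sign[1:] != sign[:-1])[0] + 1  # index into samples where direction changes
    if flips.size < 2 * n_cycles:
        logger.warning("%s: found %d reversals, expected %d; returning record unchanged",
                       record.specimen_id, flips.size, 2 * n_cycles)
        return record
    start = int(flips[2 * n_cycles - 1])  # final trough before the ramp
    if len(record) - start < min_ramp_samples:
        raise ValidationError(f"{record.specimen_id}: no terminal loading ramp after preconditioning")
    t = record.time_s[start:]
    dd = record.displacement_mm[start:]
    ff = record.force_n[start:]
    if np.any(np.diff(_smooth(dd, smooth_window)) < 0):
        logger.warning("%s: residual displacement reversals after stripping", record.specimen_id)
    # re-zero displacement at the preload crossing
    fsm = _smooth(ff, smooth_window)
    above = np.nonzero(fsm >= record.preload)[0]
    i0 = int(above[0]) if above.size else 0
    return record.with_samples(t - t[0], dd - dd[i0], ff)


def detect_failures(record: TensileRecord, min_drop_frac: float = 0.05,
                    smooth_window: int = 5, min_drop_abs: float = 2.0
                    ) -> list[tuple[int, float]]:
    """Failure events: local maxima followed by a qualifying force drop.

    A local maximum of the (smoothed) force qualifies as a failure event iff
    the force then falls by at least ``min_drop_frac`` times the running
    maximum above preload — but never less than ``min_drop_abs`` newtons —
    before the local maximum is exceeded again. The absolute floor keeps the
    relative threshold, which vanishes at the start of the ramp, from
    promoting machine-noise wiggles in the toe to failure events. Only the
    loading phase counts: the search ends at the global maximum (the
    ultimate failure), because force excursions on the post-failure tail are
    not failure events. The global maximum itself always qualifies, so a
    monotone ramp yields exactly one event and first failure equals ultimate
    load. Events are returned in order as ``(raw index, raw load)``.
    """
    f = record.force_n
    if f.size < 3:
        raise ValidationError(f"{record.specimen_id}: fewer than 3 samples")
    fs = _smooth(f, smooth_window)
    preload = record.preload
    stop = int(np.argmax(fs))  # scan the loading phase only
    events_sm: list[int] = []
    cand = 0
    runmax = fs[0]
    for j in range(1, stop + 1):
        if fs[j] > fs[cand]:
            cand = j
            runmax = max(runmax, fs[j])
        elif (cand > 0 and fs[cand] > fs[cand - 1]
              and fs[j] <= fs[cand] - max(min_drop_frac * (runmax - preload), min_drop_abs)):
            events_sm.append(cand)
            cand = j
    # map each smoothed event to the raw local maximum in its neighbourhood
    half = max(smooth_window, 1)
    events: list[int] = []
    for i in events_sm:
        lo, hi = max(0, i - half), min(f.size, i + half + 1)
        events.append(lo + int(np.argmax(f[lo:hi])))
    g = int(np.argmax(f))  # ultimate failure, first index on ties
    if g not in events:
        events.append(g)
    events = sorted(set(events))
    return [(i, float(f[i])) for i in events]


def detect_linear_region(record: TensileRecord, min_span_frac: float = 0.2,
                         r2_min: float = 0.999, end_index: int | None = None
                         ) -> tuple[int, int, float, float]:
    """Longest window before failure whose OLS fit reaches R^2 >= r2_min.

    Searches contiguous index windows ``[i, j]`` (inclusive) within
    ``[0, end_index)`` — ``end_index`` is normally the first-failure index —
    requiring a displacement span of at least ``min_span_frac`` of the
    pre-failure range. Among qualifying windows the longest wins; ties break
    to higher R^2, then to the earlier start. Returns
    ``(i_start, i_end, slope, r2)``; raises :class:`LinearRegionError` when
    nothing qualifies.
    """
    d = record.displacement_mm[:end_index]
    f = record.force_n[:end_index]
    n = d.size
    if n < 3:
        raise LinearRegionError(f"{record.specimen_id}: too few pre-failure samples")
    min_span = min_span_frac * (d[-1] - d[0])

    # prefix sums for O(1) window statistics
    c1 = np.concatenate([[0.0], np.cumsum(d)])
    c2 = np.concatenate([[0.0], np.cumsum(f)])
    c11 = np.concatenate([[0.0], np.cumsum(d * d)])
    c22 = np.concatenate([[0.0], np.cumsum(f * f)])
    c12 = np.concatenate([[0.0], np.cumsum(d * f)])

    for L in range(n, 2, -1):
        starts = np.arange(0, n - L + 1)
        ends = starts + L  # exclusive
        span_ok = (d[ends - 1] - d[starts]) >= min_span
        if not span_ok.any():
            continue
        sx = c1[ends] - c1[starts]
        sy = c2[ends] - c2[starts]
        sxx = c11[ends] - c11[starts] - sx * sx / L
        syy = c22[ends] - c22[starts] - sy * sy / L
        sxy = c12[ends] - c12[starts] - sx * sy / L
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where((sxx > 0) & (syy > 0), sxy * sxy / (sxx * syy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        ok = span_ok & (r2 >= r2_min)
        if ok.any():
            idx = np.nonzero(ok)[0]
            best = idx[np.argmax(r2[idx])]  # argmax returns first on ties -> earlier start
            slope = sxy[best] / sxx[best]
            return int(starts[best]), int(ends[best] - 1), float(slope), float(r2[best])
    raise LinearRegionError(
        f"{record.specimen_id}: no window with R^2 >= {r2_min} and span >= {min_span:.3g} mm")


def compute_stiffness(record: TensileRecord, region: tuple[int, int]) -> float:
    """OLS slope of force on displacement over an inclusive index window."""
    i, j = region
    if j - i + 1 < 3:
        raise ValidationError("linear region must contain at least 3 samples")
    d = record.displacement_mm[i:j + 1]
    f = record.force_n[i:j + 1]
    dc = d - d.mean()
    return float(np.dot(dc, f - f.mean()) / np.dot(dc, dc))


def ultimate_load(record: TensileRecord) -> tuple[float, float]:
    """Global maximum force and its displacement (earliest index on ties)."""
    i = int(np.argmax(record.force_n))
    return float(record.force_n[i]), float(record.displacement_mm[i])


def infer_failure_mode(record: TensileRecord, cliff_frac: float = 0.5,
                       cliff_window: float = 1.0, smooth_window: int = 5) -> str:
    """Classify the failure mode from the post-peak curve shape.

    ``breakage`` when the (smoothed) force falls below
    ``cliff_frac * ultimate`` within ``cliff_window`` mm after the peak,
    ``pullout`` when the decline is gradual, ``undetermined`` when fewer
    than ``cliff_window`` mm of post-peak data exist. This is a curve-shape
    heuristic; adjudicating the physical mode requires observing the test.
    """
    f = record.force_n
    d = record.displacement_mm
    peak = int(np.argmax(f))
    post = d[peak:] - d[peak]
    if post.size == 0 or post[-1] < cliff_window:
        return "undetermined"
    fs = _smooth(f, smooth_window)
    window = fs[peak:][post <= cliff_window]
    return "breakage" if window.min() < cliff_frac * f[peak] else "pullout"


def analyze_record(record: TensileRecord, thresholds: AnalysisThresholds = AnalysisThresholds(),
                   *, stripped: bool = False) -> CurveFeatures:
    """Full feature extraction for one specimen.

    Set ``stripped=True`` when the record is already a bare failure ramp.
    Raises :class:`LinearRegionError` only through the ``stiffness`` field:
    a failed region search reports stiffness/R^2 as NaN and logs the
    exclusion, keeping the load metrics.
    """
    thresholds.validate()
    ramp = record if stripped else strip_preconditioning(
        record, thresholds.n_precondition_cycles, thresholds.smooth_window)
    events = detect_failures(ramp, thresholds.min_drop_frac, thresholds.smooth_window,
                             thresholds.min_drop_abs)
    first_idx, first_load = events[0]
    ult, ult_d = ultimate_load(ramp)
    try:
        i, j, slope, r2 = detect_linear_region(
            ramp, thresholds.min_span_frac, thresholds.r2_min, end_index=first_idx)
        region = (float(ramp.displacement_mm[i]), float(ramp.displacement_mm[j]))
    except LinearRegionError as exc:
        get_logger().warning("%s: %s; excluded from stiffness statistics", record.specimen_id, exc)
        slope, r2, region = math.nan, math.nan, (math.nan, math.nan)
    mode = infer_failure_mode(ramp, thresholds.cliff_frac, thresholds.cliff_window,
                              thresholds.smooth_window)
    return CurveFeatures(
        specimen_id=record.specimen_id,
        stiffness=slope, r2_linear=r2, linear_region=region,
        first_failure_load=first_load,
        first_failure_displacement=float(ramp.displacement_mm[first_idx]),
        ultimate_load=ult, ultimate_displacement=ult_d,
        failure_mode=mode, n_partial_failures=len(events) - 1,
    )
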