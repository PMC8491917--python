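"""Reference implementations and recovery studies for self-verification.

The brute-force functions here restate the curve-analysis definitions in
their most literal O(n^2) form, independent of the optimised search paths,
so the two routes can be compared exactly. The study drivers generate
synthetic inputs under the protocol conditions and measure how well the
analysis chain recovers the known truth; both the test suite and the
acceptance script run them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from tenomech.curves import (
    AnalysisThresholds,
    LinearRegionError,
    _smooth,
    analyze_record,
    detect_failures,
    detect_linear_region,
)
from tenomech.io import TensileRecord
from tenomech.simulate import CurveParams, simulate_curve
from tenomech.stats import tukey_kramer

__all__ = [
    "CurveRecoveryResult",
    "curve_recovery_study",
    "failure_scan_bruteforce",
    "linear_region_bruteforce",
    "linear_region_oracle_mismatches",
    "failure_scan_oracle_mismatches",
    "null_familywise_error",
]


def linear_region_bruteforce(record: TensileRecord, min_span_frac: float = 0.2,
                             r2_min: float = 0.999, end_index: int | None = None
                             ) -> tuple[int, int, float, float]:
    """Exhaustive enumeration of every contiguous window (reference).

    Same selection rule as :func:`tenomech.curves.detect_linear_region` —
    longest window with span >= min_span_frac of the range and R^2 >= r2_min,
    ties to higher R^2 then earlier start — but evaluated window by window
    with an independent least-squares fit.
    """
    d = record.displacement_mm[:end_index]
    f = record.force_n[:end_index]
    n = d.size
    if n < 3:
        raise LinearRegionError("too few samples")
    min_span = min_span_frac * (d[-1] - d[0])
    best = None  # (length, r2, -start)
    for i in range(n):
        for j in range(i + 2, n):  # inclusive end, window >= 3 samples
            if d[j] - d[i] < min_span:
                continue
            x, y = d[i:j + 1], f[i:j + 1]
            xc = x - x.mean()
            yc = y - y.mean()
            sxx = float(np.dot(xc, xc))
            syy = float(np.dot(yc, yc))
            sxy = float(np.dot(xc, yc))
            r2 = (sxy * sxy / (sxx * syy)) if sxx > 0 and syy > 0 else 0.0
            r2 = min(max(r2, 0.0), 1.0)
            if r2 < r2_min:
                continue
            key = (j - i + 1, r2, -i)
            if best is None or key > best[0]:
                best = (key, (i, j, sxy / sxx, r2))
    if best is None:
        raise LinearRegionError("no linear region (brute force)")
    return best[1]


def failure_scan_bruteforce(record: TensileRecord, min_drop_frac: float = 0.05,
                            smooth_window: int = 5, min_drop_abs: float = 2.0
                            ) -> list[tuple[int, float]]:
    """Literal local-max-plus-drop scan (reference for detect_failures).

    For every strict local maximum of the smoothed force on the loading
    phase (up to the global maximum), look forward: the maximum qualifies
    iff the force falls by the drop threshold before any later sample
    exceeds it. Thresholds and the raw-sample refinement match the
    production rule.
    """
    f = record.force_n
    fs = _smooth(f, smooth_window)
    preload = record.preload
    n = int(np.argmax(fs)) + 1  # loading phase only
    prefix_max = np.maximum.accumulate(fs)
    qualifying: list[int] = []
    start = 0
    while start < n:
        hit = None
        for j in range(start + 1, n):
            # current candidate: first attainment of the segment maximum,
            # recomputed from scratch (no carried state)
            cand = start + int(np.argmax(fs[start:j + 1]))
            thresh = max(min_drop_frac * (prefix_max[j] - preload), min_drop_abs)
            if (cand != j and cand > 0 and fs[cand] > fs[cand - 1]
                    and fs[j] <= fs[cand] - thresh):
                hit = (cand, j)
                break
        if hit is None:
            break
        qualifying.append(hit[0])
        start = hit[1]
    half = max(smooth_window, 1)
    events = []
    for i in qualifying:
        lo, hi = max(0, i - half), min(f.size, i + half + 1)
        events.append(lo + int(np.argmax(f[lo:hi])))
    g = int(np.argmax(f))
    if g not in events:
        events.append(g)
    return [(i, float(f[i])) for i in sorted(set(events))]


# ---------------------------------------------------------------------------
# studies


@dataclass
class CurveRecoveryResult:
    """Aggregate recovery errors over a batch of simulated curves."""

    n_curves: int
    n_no_region: int
    median_rel_stiffness_error: float   # fraction
    max_rel_stiffness_error: float      # fraction
    max_abs_ultimate_error: float       # N
    first_exceeds_ultimate: int         # count of invariant violations
    mode_agreement: float               # fraction


def curve_recovery_study(seed: int = 0, n_curves: int = 200,
                         noise_sd: float = 0.5,
                         thresholds: AnalysisThresholds = AnalysisThresholds()
                         ) -> CurveRecoveryResult:
    """Recover stiffness and loads from simulated curves with known truth.

    Conditions follow the emulated protocol: stiffness uniform on
    [20, 80] N/mm, ultimate load uniform on [80, 300] N, machine noise
    0.5 N, default thresholds, preconditioning included and stripped.
    """
    rng = np.random.default_rng(seed)
    rel_err: list[float] = []
    ult_err: list[float] = []
    no_region = 0
    viol = 0
    mode_ok = 0
    for i in range(n_curves):
        k = float(rng.uniform(20.0, 80.0))
        u = float(rng.uniform(80.0, 300.0))
        params = CurveParams(k_true=k, ultimate_load_true=u, noise_sd=noise_sd,
                             seed=int(rng.integers(0, 2**31 - 1)))
        record, truth = simulate_curve(params)
        feats = analyze_record(record, thresholds)
        if np.isnan(feats.stiffness):
            no_region += 1
        else:
            rel_err.append(abs(feats.stiffness - truth.true_stiffness) / truth.true_stiffness)
        ult_err.append(abs(feats.ultimate_load - truth.true_ultimate_load))
        if feats.first_failure_load > feats.ultimate_load:
            viol += 1
        if feats.failure_mode == truth.post_mode:
            mode_ok += 1
    return CurveRecoveryResult(
        n_curves=n_curves, n_no_region=no_region,
        median_rel_stiffness_error=float(np.median(rel_err)),
        max_rel_stiffness_error=float(np.max(rel_err)),
        max_abs_ultimate_error=float(np.max(ult_err)),
        first_exceeds_ultimate=viol,
        mode_agreement=mode_ok / n_curves,
    )


def _oracle_records(seed: int, n_records: int, max_samples: int = 500):
    """Small noisy records (some pure noise) for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    for i in range(n_records):
        if i % 5 == 4:
            # pure noise around a constant force: no linear region expected
            n = int(rng.integers(50, max_samples))
            d = np.cumsum(np.full(n, 0.01))
            f = 10.0 + rng.normal(0, 1.0, n)
            t = d / (100.0 / 60.0)
            yield TensileRecord(f"noise-{i}", t, d, f).validate()
        else:
            k = float(rng.uniform(20.0, 80.0))
            u = float(rng.uniform(40.0, 90.0))
            drops = ()
            if i % 3 == 0:
                # place the partial failure well inside the linear rise
                d_fail = 0.5 + float(rng.uniform(0.4, 0.8)) * (u - 2.0) / k
                if d_fail > 1.05:
                    drops = ((d_fail, float(rng.uniform(0.15, 0.4))),)
            params = CurveParams(k_true=k, ultimate_load_true=u, noise_sd=0.5,
                                 partial_failures=drops, step=0.02,
                                 precondition_cycles=0,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            rec, _ = simulate_curve(params)
            yield rec


def linear_region_oracle_mismatches(seed: int = 0, n_records: int = 50,
                                    thresholds: AnalysisThresholds = AnalysisThresholds()
                                    ) -> int:
    """Count records where the fast window search and brute force disagree."""
    mismatches = 0
    for rec in _oracle_records(seed, n_records):
        try:
            fast = detect_linear_region(rec, thresholds.min_span_frac, thresholds.r2_min)
            fast_res: tuple | None = fast[:2]
        except LinearRegionError:
            fast_res = None
        try:
            slow = linear_region_bruteforce(rec, thresholds.min_span_frac, thresholds.r2_min)
            slow_res: tuple | None = slow[:2]
        except LinearRegionError:
            slow_res = None
        if fast_res != slow_res:
            mismatches += 1
        elif fast_res is not None and abs(fast[2] - slow[2]) > 1e-9 * max(1.0, abs(slow[2])):
            mismatches += 1
    return mismatches


def failure_scan_oracle_mismatches(seed: int = 1, n_records: int = 50,
                                   thresholds: AnalysisThresholds = AnalysisThresholds()
                                   ) -> int:
    """Count records where the event scan and the brute-force scan disagree."""
    mismatches = 0
    for rec in _oracle_records(seed, n_records):
        fast = detect_failures(rec, thresholds.min_drop_frac,
                               thresholds.smooth_window, thresholds.min_drop_abs)
        slow = failure_scan_bruteforce(rec, thresholds.min_drop_frac,
                                       thresholds.smooth_window, thresholds.min_drop_abs)
        if fast != slow:
            mismatches += 1
    return mismatches


def null_familywise_error(seed: int = 0, n_replicates: int = 5000,
                          n_groups: int = 3, n_per_group: int = 12,
                          alpha: float = 0.05) -> float:
    """Monte-Carlo family-wise error of Tukey–Kramer under the global null.

    All groups share the same normal distribution; a replicate counts as a
    family-wise error when any pairwise comparison is declared significant.
    A calibrated procedure should land near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(n_groups)]
    hits = 0
    for _ in range(n_replicates):
        groups = {lab: rng.normal(0.0, 1.0, n_per_group) for lab in labels}
        results = tukey_kramer(groups, alpha)
        if any(r.significant for r in results):
            hits += 1
    return hits / n_replicates
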