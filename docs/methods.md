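# Methods

## The measurement problem

A side-to-side tenorrhaphy is loaded to failure in a tensile machine while
force (N) and crosshead displacement (mm) are recorded. The protocol this
package emulates applies a 2 N preload, five preconditioning cycles with an
amplitude of 5% of the clamp distance at 10 mm/min, then elongates the
construct to failure at 100 mm/min. From each load-deformation curve three
structural metrics are read: the stiffness (slope of the linear elastic
region), the first failure load (first local maximum followed by a real
force drop) and the ultimate load (global maximum). Caliper diameters of
donor tendon, recipient tendon and repair zone give the bulk ratio. Groups
of repair techniques are compared metric by metric with one-way ANOVA and
Tukey–Kramer tests at α = 0.05.

All internal units are fixed to s / mm / N; unit conversion happens only at
the I/O boundary, driven by a declared dialect.

## Synthetic curve model

The noise-free force model is piecewise and chosen for analytic
tractability — every derived truth is in closed form:

* **Toe region**, `0 ≤ d ≤ L` with exponent `e ≥ 1`:
  `F(d) = P + k·d^e / (e·L^(e−1))`. Its derivative at `d = L` is exactly
  `k`, making the junction C¹-continuous.
* **Linear region**: `F(d) = P + k·(d − L·(1 − 1/e))`.
* **Partial failures**: at a configured displacement the force above
  preload drops by a fraction and the curve resumes at slope `k`. Each
  pre-drop peak must stay below the ultimate load.
* **Ultimate failure**: the displacement where the active branch reaches
  the configured ultimate load; that exact point is inserted into the
  sampling grid so the noise-free sampled maximum equals the truth to
  machine precision.
* **Post-peak**: pull-out decays linearly (default 25 N/mm); breakage
  collapses below preload within one sample and holds a small residual.

Gaussian noise (default SD 0.5 N, a realistic machine/grip jitter for
loads of order 100 N) is added to force. Sampling is uniform in
displacement (default step 0.01 mm); velocity only sets the time column.
Preconditioning cycles are triangular displacement waves whose force
follows the pre-failure branch of the same model. The default clamp
distance (20 mm) makes the 5% preconditioning amplitude coincide with the
toe span, mirroring real protocols where preconditioning loads are a small
fraction of the failure load; the simulator rejects parameter sets whose
preconditioning would exceed the ultimate load.

Cohorts draw per-specimen stiffness, ultimate load and bulk ratio from
normals truncated at 3 SD and at physical lower bounds. Repair-zone
diameters are solved from the drawn bulk ratio, so group-level bulk-ratio
truths are exact. The default three-group cohort (12 specimens per group)
encodes the qualitative pattern the emulated experiment reports — the
woven technique stiffest, strongest and slimmest; the classical weave the
opposite — with magnitudes chosen as plausible for porcine extensor
tendons (stiffness 25/35/45 N/mm, ultimate 110/150/190 N, bulk ratio
140/125/105%); the underlying study's numeric table is not publicly
available, so these are illustrative defaults, not reproductions.

All randomness uses numpy's PCG64 (`default_rng(seed)`); the generator is
part of the public contract, which is what makes reports byte-identical
across runs and platforms given a seed.

## Curve analysis

**Preconditioning strip.** Displacement reversals are sign changes of the
smoothed displacement increment; after `2·n_cycles` reversals the
remainder is the failure ramp, re-zeroed at the preload crossing. Fewer
reversals than expected ⇒ the record is returned unchanged with a warning,
which also makes the operation idempotent. Reversals without a terminal
ramp raise an error.

**Failure events.** A local maximum of the (smoothed, width-5) force
qualifies as a failure event iff the force then falls by at least
`min_drop_frac` (default 5%) of the running maximum above preload — but
never less than `min_drop_abs` (default 2 N) — before the maximum is
exceeded again. The absolute floor exists because the relative threshold
vanishes at the start of the ramp, where any noise wiggle would otherwise
qualify. Only the loading phase (up to the global maximum) is scanned:
force excursions on the post-failure tail are not failure events. The
global maximum always counts, so a monotone ramp yields exactly one event
and first failure equals ultimate — the behaviour expected of repairs that
fail by gradual pull-out. Reported loads are always read from the raw,
unfiltered samples; smoothing is for detection only.

**Linear region and stiffness.** The region is the *longest* contiguous
sample window before the first failure whose OLS fit of force on
displacement reaches `R² ≥ r2_min`, subject to a minimum span of 20% of
the pre-failure displacement range; ties break to higher R², then to the
earlier start. The fast search (prefix sums, windows enumerated by
descending length) is checked exactly against a naive O(n²) enumeration.
The default `r2_min = 0.999` was calibrated on simulated curves at the
protocol noise level: at 0.99 the longest qualifying window reaches far
into the curved toe and biases the slope low by ~5%, while beyond ~0.9995
genuine linear windows of low-stiffness noisy specimens start failing the
criterion entirely. At 0.999 the median recovery error is ~1.7% with no
specimens lost. Specimens with no qualifying window are excluded from
stiffness statistics (logged) but keep their load metrics.

**Failure mode.** A curve-shape heuristic, clearly labelled as such:
breakage iff the smoothed force falls below half the ultimate load within
1 mm of the peak; pull-out iff the decline is gradual; undetermined when
less than 1 mm of post-peak data exists. Adjudicating the physical mode
requires watching the test; the heuristic recovers the simulator's mode
exactly on noise-free curves and is meant for triage, not ground truth.

## Geometry

Cross-sections are elliptical from the two orthogonal caliper diameters
(`π·d₁·d₂/4`; circular fallback for a single diameter). The bulk ratio
divides the repair area by the **sum** of the native areas (the repair
replaces the pair of overlapping tendons); a `mean` denominator variant is
provided since caliper-based conventions differ between labs. The ratio is
homogeneous of degree zero, hence exactly scale-invariant — a property the
tests assert.

## Statistics

ANOVA and Tukey–Kramer are implemented from their defining formulas so
each piece is testable against independent oracles. For each pair,

```
q = |m_a − m_b| / sqrt( MS_within/2 · (1/n_a + 1/n_b) )
```

with the adjusted p-value from the studentized-range distribution with
`k` groups and `N − k` error degrees of freedom; with equal `n` this is
classical Tukey HSD. The studentized-range CDF is evaluated by direct
Gauss–Legendre quadrature of the classical double integral (96 inner
normal nodes on [−8.5, 8.5], 64 outer chi nodes over ±12 SD of the scale
variable); it agrees with scipy's implementation to ~1e-14 while being
orders of magnitude faster, which is what makes a 5000-replicate
family-wise-error calibration cheap. No normality or homoscedasticity
pre-tests gate the analysis (none are part of the emulated protocol).

**Compact letters.** Letter columns are cliques of the
"not-significantly-different" graph; the implementation finds the smallest
set of maximal cliques covering every non-significant pair and every
group, so the invariant *share a letter ⇔ not significantly different*
holds by construction and the letter count is minimal (verified against an
exhaustive assignment search for 3 and 4 groups). Letters are ordered
a, b, c… by descending group mean, so "a" marks the best-performing
cluster. The search is exponential in the number of groups, which is
irrelevant at the 3–6 groups such experiments use.

## Block randomization

Each limb contributes four tendons — lateral (I) and medial (IV) as the
smaller-caliber donors, median (II, III) as recipients — and hosts two
sutures, each pairing the proximal half of one tendon with the distal half
of the other. Balance is enforced by construction: limbs are split evenly
between the two possible donor–recipient pairing patterns, and within each
pattern every combination column receives every group exactly once per
block; randomness only permutes assignments inside blocks. Feasibility
therefore requires the limb count to be a multiple of twice the group
count (6, 12, 18… for three groups); an infeasible count raises an error
naming the smallest feasible one. An independent checker validates any
plan row-by-row and is exercised against hand-corrupted plans.

## What the synthetic data does and does not show

The generator reproduces the *structure* of real records — toe, linear
rise, discrete drops, pull-out tails, preload offset, preconditioning,
machine noise — with known truth, so passing tests demonstrate that the
analysis recovers what the curve model encodes at the protocol noise
level. Real tendons add viscoelasticity (rate dependence, hysteresis
between preconditioning cycles), grip slippage artefacts, non-Gaussian
noise and drifting baselines, none of which are modelled; recovery rates
here are an upper bound on real-data performance. The failure-mode
heuristic in particular substitutes for direct observation of the test.

## Numerical and scope notes

* Window R² is computed from prefix sums in double precision and clipped
  to [0, 1]; windows with zero force or displacement variance are rejected.
* Degenerate statistics are defined explicitly: identical groups give
  F = 0, p = 1; zero within-group variance with distinct means gives
  p_adj = 0; single-value samples report SD 0 with a warning.
* The recovery studies use 200 curves, the FWER calibration 5000
  replicates, and the oracle-equivalence checks 50 records of ≤ ~500
  samples — sizes at which the brute-force references stay exact and fast.
* Out of scope: material (stress/strain) normalisation, viscoelastic
  constitutive modelling, cyclic-fatigue metrics, nonparametric or
  mixed-model statistics, and any claim about the surgical techniques
  themselves beyond what the structural metrics express.
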