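"""Group summaries, one-way ANOVA, Tukey–Kramer comparisons, letter display.

The ANOVA and Tukey–Kramer stages are implemented from their defining
formulas, with the studentized-range distribution evaluated by direct
numerical quadrature, so each piece can be tested against independent
oracles. The compact letter display assigns the minimal number of letters
such that two groups share a letter if and only if their pairwise
comparison is not significant; letter 'a' marks the group with the highest
mean.

Studentized range. For k groups and nu error degrees of freedom the CDF is

    P(Q <= q) = Int_0^inf f_nu(s) * k * Int phi(z) [Phi(z) - Phi(z - q s)]^(k-1) dz ds

where s is distributed as sqrt(chi2_nu / nu). Both integrals are evaluated
with Gauss–Legendre rules: the inner integrand is dominated by phi(z), so a
fixed node set on [-8.5, 8.5] suffices; the outer density is integrated
over +-12 SD of s around 1 (clipped at 0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, ndtr
from scipy.stats import f as f_dist
from scipy.optimize import brentq

from tenomech.io import ValidationError, get_logger

__all__ = [
    "AnovaTable",
    "GroupComparison",
    "LetterAssignment",
    "PairwiseResult",
    "compact_letter_display",
    "compare_groups",
    "one_way_anova",
    "studentized_range_cdf",
    "studentized_range_ppf",
    "studentized_range_sf",
    "summarize",
    "tukey_kramer",
]


# ---------------------------------------------------------------------------
# studentized range distribution

_NZ = 96     # inner (normal) nodes
_NS = 64     # outer (chi) nodes


@lru_cache(maxsize=None)
def _z_nodes() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(_NZ)
    lo, hi = -8.5, 8.5
    z = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wz = 0.5 * (hi - lo) * w
    phi = np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    return z, wz * phi


@lru_cache(maxsize=None)
def _s_nodes(df: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for integrating over s ~ sqrt(chi2_df / df)."""
    x, w = np.polynomial.legendre.leggauss(_NS)
    sd = 1.0 / math.sqrt(2.0 * df)
    lo, hi = max(1e-8, 1.0 - 12.0 * sd), 1.0 + 12.0 * sd
    s = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    ws = 0.5 * (hi - lo) * w
    # density of s: 2 (df/2)^(df/2) / Gamma(df/2) * s^(df-1) exp(-df s^2 / 2)
    logf = (math.log(2.0) + 0.5 * df * math.log(df / 2.0) - gammaln(df / 2.0)
            + (df - 1.0) * np.log(s) - 0.5 * df * s * s)
    return s, ws * np.exp(logf)


def studentized_range_cdf(q, k: int, df: float) -> np.ndarray | float:
    """CDF of the studentized range of k groups with df error dof."""
    if k < 2:
        raise ValidationError("studentized range needs k >= 2")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    z, wz = _z_nodes()
    out = np.zeros(q_arr.shape, dtype=float)
    pos = q_arr > 0
    qp = q_arr[pos]
    if math.isinf(df):
        s = np.ones(1)
        ws = np.ones(1)
    else:
        s, ws = _s_nodes(int(df))
    res = np.empty(qp.size)
    chunk = 256
    phi_z = ndtr(z)
    for a in range(0, qp.size, chunk):
        qc = qp[a:a + chunk]                        # (m,)
        arg = z[None, None, :] - qc[:, None, None] * s[None, :, None]
        inner = (phi_z[None, None, :] - ndtr(arg)) ** (k - 1)
        iz = inner @ wz                             # (m, ns)
        res[a:a + chunk] = k * (iz @ ws)
    out[pos] = np.clip(res, 0.0, 1.0)
    return out if np.ndim(q) else float(out[0])


def studentized_range_sf(q, k: int, df: float) -> np.ndarray | float:
    """Survival function (Tukey-adjusted p-value for a range statistic q)."""
    cdf = studentized_range_cdf(q, k, df)
    return 1.0 - cdf


def studentized_range_ppf(p: float, k: int, df: float) -> float:
    """Quantile of the studentized range (inverse CDF), by root bracketing."""
    if not 0 < p < 1:
        raise ValidationError("p must lie in (0, 1)")
    return float(brentq(lambda q: studentized_range_cdf(q, k, df) - p, 1e-6, 100.0,
                        xtol=1e-10))


# ---------------------------------------------------------------------------
# summaries and ANOVA


def summarize(values: Iterable[float]) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator); n=1 reports SD 0 with a warning."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    if x.size == 1:
        get_logger().warning("sample of size 1: SD reported as 0")
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1))


@dataclass(frozen=True)
class AnovaTable:
    """Classical fixed-effects one-way decomposition."""

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaTable:
    """One-way fixed-effects ANOVA across >= 2 groups, each with n >= 2."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = {}
    for label, vals in groups.items():
        x = np.asarray(list(vals), dtype=float)
        if x.size < 2:
            raise ValidationError(f"group {label!r} has n={x.size} < 2")
        arrays[label] = x
    allx = np.concatenate(list(arrays.values()))
    grand = allx.mean()
    ss_between = sum(x.size * (x.mean() - grand) ** 2 for x in arrays.values())
    ss_within = sum(float(((x - x.mean()) ** 2).sum()) for x in arrays.values())
    ss_total = float(((allx - grand) ** 2).sum())
    df_b = len(arrays) - 1
    df_w = allx.size - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w > 0:
        F = ms_b / ms_w
        p = float(f_dist.sf(F, df_b, df_w))
    elif ms_b > 0:
        F, p = math.inf, 0.0
    else:
        F, p = 0.0, 1.0
    return AnovaTable(float(ss_between), ss_within, ss_total, df_b, df_w,
                      float(ms_b), float(ms_w), float(F), p)


# ---------------------------------------------------------------------------
# Tukey–Kramer and letters


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey–Kramer comparison; mean_diff = mean(group_a) - mean(group_b)."""

    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    p_adj: float
    significant: bool


def tukey_kramer(groups: Mapping[str, Sequence[float]], alpha: float = 0.05
                 ) -> list[PairwiseResult]:
    """All-pairs comparisons via the studentized range, valid for unequal n.

    For each pair, ``q = |mean_a - mean_b| / sqrt(MS_within/2 * (1/n_a + 1/n_b))``
    with MS_within from the pooled one-way ANOVA; the adjusted p-value is the
    studentized-range survival function with k groups and N-k dof. With
    equal group sizes this reduces to classical Tukey HSD.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    table = one_way_anova(groups)
    arrays = {label: np.asarray(list(v), dtype=float) for label, v in groups.items()}
    k = len(arrays)
    labels = list(arrays)
    pairs = list(itertools.combinations(labels, 2))
    diffs = np.array([arrays[a].mean() - arrays[b].mean() for a, b in pairs])
    if table.ms_within > 0:
        ses = np.array([math.sqrt(table.ms_within / 2.0
                                  * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
                        for a, b in pairs])
        q = np.abs(diffs) / ses
        p = np.clip(studentized_range_sf(q, k, table.df_within), 0.0, 1.0)
    else:  # degenerate: zero within-group variance
        q = np.where(diffs == 0, 0.0, math.inf)
        p = np.where(diffs == 0, 1.0, 0.0)
    return [PairwiseResult(a, b, float(dd), float(qq), float(pp), bool(pp < alpha))
            for (a, b), dd, qq, pp in zip(pairs, diffs, q, p)]


@dataclass(frozen=True)
class LetterAssignment:
    """Per-group letter sets; groups share a letter iff not significantly different."""

    letters: dict[str, str]

    def share(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _maximal_cliques(vertices: list[str], adj: dict[str, set[str]]) -> list[frozenset[str]]:
    """Bron–Kerbosch with deterministic ordering."""
    cliques: list[frozenset[str]] = []

    def expand(r: set[str], p: list[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in list(p):
            expand(r | {v}, [u for u in p if u in adj[v]], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), list(vertices), set())
    return cliques


def compact_letter_display(pairwise: Sequence[PairwiseResult],
                           means: Mapping[str, float]) -> LetterAssignment:
    """Minimal letter assignment consistent with the pairwise results.

    Letters are whole-group cliques of the "not significantly different"
    graph; the smallest set of cliques covering every non-significant pair
    (and every group) is found exactly, then letters are ordered a, b, c, ...
    by descending group mean so 'a' marks the best-performing cluster.
    """
    labels = sorted(means, key=lambda g: (-means[g], g))
    seen = {r.group_a for r in pairwise} | {r.group_b for r in pairwise}
    if seen - set(labels):
        raise ValidationError(f"pairwise results mention unknown groups {seen - set(labels)}")
    adj: dict[str, set[str]] = {g: set() for g in labels}
    nonsig_edges: set[frozenset[str]] = set()
    for r in pairwise:
        if not r.significant:
            adj[r.group_a].add(r.group_b)
            adj[r.group_b].add(r.group_a)
            nonsig_edges.add(frozenset((r.group_a, r.group_b)))
    cliques = _maximal_cliques(labels, adj)
    cliques.sort(key=lambda c: (min(labels.index(g) for g in c), -len(c)))

    def covers(subset: tuple[frozenset[str], ...]) -> bool:
        verts = set().union(*subset)
        if verts != set(labels):
            return False
        return all(any(e <= c for c in subset) for e in nonsig_edges)

    chosen: tuple[frozenset[str], ...] | None = None
    for r in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, r):
            if covers(combo):
                chosen = combo
                break
        if chosen:
            break
    assert chosen is not None  # all-singletons cover always exists
    ordered = sorted(chosen, key=lambda c: (min(labels.index(g) for g in c), -len(c)))
    out: dict[str, list[str]] = {g: [] for g in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", ordered):
        for g in clique:
            out[g].append(letter)
    return LetterAssignment({g: "".join(sorted(ls)) for g, ls in out.items()})


# ---------------------------------------------------------------------------
# convenience aggregate


@dataclass
class GroupComparison:
    """Everything the summary table needs for one metric."""

    metric: str
    n: dict[str, int]
    summaries: dict[str, tuple[float, float]]
    anova: AnovaTable
    pairwise: list[PairwiseResult]
    letters: dict[str, str]
    alpha: float = 0.05


def compare_groups(data: Mapping[str, Sequence[float]], alpha: float = 0.05,
                   metric: str = "metric") -> GroupComparison:
    """Summaries + ANOVA + Tukey–Kramer + letters for one metric."""
    arrays = {g: np.asarray(list(v), dtype=float) for g, v in data.items()}
    summaries = {g: summarize(x) for g, x in arrays.items()}
    anova = one_way_anova(arrays)
    pairwise = tukey_kramer(arrays, alpha)
    letters = compact_letter_display(pairwise, {g: s[0] for g, s in summaries.items()})
    return GroupComparison(
        metric=metric,
        n={g: int(x.size) for g, x in arrays.items()},
        summaries=summaries, anova=anova, pairwise=pairwise,
        letters=letters.letters, alpha=alpha,
    )
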