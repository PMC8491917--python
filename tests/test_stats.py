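import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import min_letters_bruteforce
from tenomech.io import ValidationError
from tenomech.stats import (
    PairwiseResult,
    compact_letter_display,
    compare_groups,
    one_way_anova,
    studentized_range_cdf,
    studentized_range_ppf,
    summarize,
    tukey_kramer,
)


class TestSummarize:
    def test_hand_case(self):
        assert summarize([2, 4, 6]) == (4.0, 2.0)

    def test_singleton_sd_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert summarize([5.0]) == (5.0, 0.0)
        assert "size 1" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        t = one_way_anova({"a": [3, 3, 3], "b": [3, 3, 3]})
        assert t.F == 0.0 and t.p == 1.0

    def test_hand_computed_decomposition(self):
        t = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert t.ss_between == pytest.approx(54.0)
        assert t.ss_within == pytest.approx(6.0)
        assert (t.df_between, t.df_within) == (2, 6)
        assert t.F == pytest.approx(27.0)
        assert t.p == pytest.approx(0.001, rel=0.05)

    def test_order_within_groups_irrelevant(self):
        a = one_way_anova({"a": [1, 2, 3], "b": [6, 5, 4]})
        b = one_way_anova({"a": [3, 1, 2], "b": [4, 6, 5]})
        assert a == b

    def test_small_group_named_in_error(self):
        with pytest.raises(ValidationError, match="tiny"):
            one_way_anova({"ok": [1, 2, 3], "tiny": [1]})

    @settings(derandomize=True, max_examples=100)
    @given(data=st.lists(
        st.lists(st.floats(min_value=-1e3, max_value=1e3,
                           allow_nan=False, width=32), min_size=2, max_size=10),
        min_size=2, max_size=5))
    def test_sum_of_squares_identity(self, data):
        groups = {f"g{i}": vals for i, vals in enumerate(data)}
        t = one_way_anova(groups)
        assert t.ss_total == pytest.approx(t.ss_between + t.ss_within,
                                           rel=1e-9, abs=1e-7)


class TestStudentizedRange:
    def test_matches_scipy_distribution(self):
        from scipy.stats import studentized_range

        q = np.array([1.0, 2.0, 3.5, 5.0])
        for k, df in [(3, 33), (4, 8), (2, 60)]:
            np.testing.assert_allclose(studentized_range_cdf(q, k, df),
                                       studentized_range.cdf(q, k, df), atol=1e-8)

    def test_ppf_roundtrip(self):
        q = studentized_range_ppf(0.95, 3, 33)
        assert studentized_range_cdf(q, 3, 33) == pytest.approx(0.95, abs=1e-9)


class TestTukeyKramer:
    def test_equal_n_reduces_to_tukey_hsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(1)
        groups = {g: rng.normal(mu, 2.0, 12) for g, mu in [("a", 10), ("b", 12), ("c", 15)]}
        mine = {frozenset((r.group_a, r.group_b)): r for r in tukey_kramer(groups)}
        endog = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [12, 12, 12])
        ref = pairwise_tukeyhsd(endog, labels, alpha=0.05)
        for (g1, g2), diff, p in zip(itertools.combinations(ref.groupsunique, 2),
                                     ref.meandiffs, ref.pvalues):
            r = mine[frozenset((g1, g2))]
            assert abs(r.mean_diff) == pytest.approx(abs(diff), rel=1e-12)
            assert r.p_adj == pytest.approx(p, abs=1e-6)

    def test_hand_case_extreme_pair(self):
        res = tukey_kramer({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        by = {frozenset((r.group_a, r.group_b)): r for r in res}
        extreme = by[frozenset(("a", "c"))]
        assert abs(extreme.mean_diff) == pytest.approx(6.0)
        assert extreme.q_stat == pytest.approx(6.0 / math.sqrt(1.0 / 3.0), rel=1e-12)
        assert extreme.significant

    def test_identical_groups_not_significant(self):
        res = tukey_kramer({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res[0].p_adj == pytest.approx(1.0, abs=1e-9)
        assert not res[0].significant

    def test_p_monotone_in_mean_separation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 10)
        last = 1.1
        for shift in (0.5, 1.0, 2.0, 4.0):
            res = tukey_kramer({"a": base, "b": base + shift})
            assert res[0].p_adj < last
            last = res[0].p_adj


class TestCompactLetterDisplay:
    @staticmethod
    def _pairwise(labels, sig):
        out = []
        for a, b in itertools.combinations(labels, 2):
            s = frozenset((a, b)) in sig
            out.append(PairwiseResult(a, b, 1.0, 1.0, 0.01 if s else 0.5, s))
        return out

    def test_all_significant_distinct_letters(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        sig = {frozenset(p) for p in itertools.combinations(means, 2)}
        la = compact_letter_display(self._pairwise(means, sig), means)
        assert la.letters == {"x": "a", "y": "b", "z": "c"}

    def test_none_significant_single_letter(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        la = compact_letter_display(self._pairwise(means, set()), means)
        assert la.letters == {"x": "a", "y": "a", "z": "a"}

    def test_chain_pattern_shares_middle(self):
        means = {"WF": 3.0, "FR": 2.0, "PT": 1.0}
        sig = {frozenset(("WF", "PT"))}
        la = compact_letter_display(self._pairwise(means, sig), means)
        assert la.letters == {"WF": "a", "FR": "ab", "PT": "b"}

    def test_minimal_and_consistent_for_all_k3_patterns(self):
        labels = ["g1", "g2", "g3"]
        means = {"g1": 3.0, "g2": 2.0, "g3": 1.0}
        pairs = list(itertools.combinations(labels, 2))
        for mask in range(2 ** len(pairs)):
            sig = {frozenset(p) for i, p in enumerate(pairs) if mask >> i & 1}
            la = compact_letter_display(self._pairwise(labels, sig), means)
            for a, b in pairs:
                assert la.share(a, b) == (frozenset((a, b)) not in sig)
            n_letters = len(set("".join(la.letters.values())))
            assert n_letters == min_letters_bruteforce(labels, sig)


def test_compare_groups_wiring():
    comp = compare_groups({"lo": [1.0, 1.1, 0.9], "hi": [9.0, 9.1, 8.9]}, metric="demo")
    assert comp.metric == "demo"
    assert comp.letters == {"hi": "a", "lo": "b"}
    assert comp.anova.p < 0.001
    assert comp.summaries["hi"][0] == pytest.approx(9.0)
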