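"""Multi-group comparison on a small hand-checkable dataset.

Three groups with clearly separated means: the ANOVA decomposition can be
verified by hand (SS_between = 54, SS_within = 6, F = 27), and the extreme
pair is the only question for the letter display.
"""

from tenomech import compare_groups

comp = compare_groups({"low": [1, 2, 3], "mid": [4, 5, 6], "high": [7, 8, 9]},
                      alpha=0.05, metric="demo")

a = comp.anova
print(f"ANOVA: SS_between = {a.ss_between:.0f}, SS_within = {a.ss_within:.0f}, "
      f"F({a.df_between},{a.df_within}) = {a.F:.0f}, p = {a.p:.4f}")
for r in comp.pairwise:
    star = "*" if r.significant else " "
    print(f"  {r.group_a:>4} vs {r.group_b:<4} diff = {r.mean_diff:+.1f}  "
          f"q = {r.q_stat:5.2f}  p_adj = {r.p_adj:.4f} {star}")
print("letters:", comp.letters)

# All three pairwise comparisons are significant here, so each group gets
# its own letter, ordered a > b > c by descending mean.
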