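"""Full pipeline demo: three technique groups, twelve specimens each.

Simulates a cohort emulating the reference experiment (Pulvertaft,
Fridén and Woven-Fridén side-to-side tenorrhaphies), analyzes every
curve, computes bulk ratios, and compares the groups with one-way ANOVA,
Tukey–Kramer tests and compact letters. Output tables and letter-annotated
bar charts land in ./report_demo.
"""

from tenomech import RunConfig, run

bundle = run(RunConfig(), "report_demo")

print(f"{len(bundle.features)} specimens analyzed\n")
for metric, comp in bundle.comparisons.items():
    a = comp.anova
    print(f"{metric}: ANOVA F({a.df_between},{a.df_within}) = {a.F:.1f}, p = {a.p:.2g}")
    for g in ("PT", "FR", "WF"):
        mean, sd = comp.summaries[g]
        print(f"   {g}: {mean:7.1f} ({sd:5.1f})  {comp.letters[g]}")

# Groups that share no letter differ significantly (alpha 0.05, Tukey-
# Kramer adjusted). With the default cohort the woven technique shows the
# highest ultimate load and the lowest bulk ratio, the Pulvertaft weave the
# opposite - the qualitative pattern the simulation emulates.
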