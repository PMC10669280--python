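"""Dose-response plate analysed with ANOVA + Dunnett's many-to-one test.

Simulates a TMRM plate with three doses of a hyperpolarising treatment
(+5 / +15 / +30% membrane potential), normalises to the untreated
control, and reports which doses differ significantly from control after
familywise-error correction.
"""

from mitoquant import dunnett_vs_control, gen_plate, GroupData, tmrm_plate_potential

plate, truth = gen_plate(
    {"untreated": 100.0, "dose_0.3uM": 105.0, "dose_2.23uM": 115.0, "dose_6uM": 130.0},
    control="untreated",
    noise_sigma=5.0,
    replicates=6,
    seed=21,
)
per_sample, per_group = tmrm_plate_potential(plate)
print(per_group.round(1).to_string(index=False))
print()

rows = per_sample[per_sample["role"].isin(["sample", "untreated_control"])]
groups = [
    GroupData(lab, rows.loc[rows["group"] == lab, "potential_pct"].to_numpy(),
              is_control=(lab == "untreated"))
    for lab in ("untreated", "dose_0.3uM", "dose_2.23uM", "dose_6uM")
]
res = dunnett_vs_control(groups, seed=0)
a = res.anova
print(f"one-way ANOVA: F({a.df_between},{a.df_within}) = {a.F:.2f}, p = {a.p:.2g}")
for c in res.comparisons:
    print(f"  {c.label:>12} vs untreated: {c.mean_diff:+6.1f}% "
          f"adj. p = {c.p_adjusted:.4f} {c.stars}")

# Dunnett's method controls the familywise error across the three
# dose-vs-control comparisons; stars follow the p <= 0.05/0.01/0.001/0.0001
# convention.
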