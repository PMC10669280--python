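"""Quantify erythrocyte haemolysis from a 415 nm absorbance plate.

Simulates a plate where a treatment lyses ~1% of erythrocytes (released
haemoglobin absorbance scaled between a saline blank at 0% and a 1%
Triton X-100 positive control at 100%), then tests the treatment against
the untreated control.
"""

from mitoquant import gen_plate, haemolysis_table, dunnett_vs_control, groups_from_frame

blank, triton = 0.05, 1.05
plate, _ = gen_plate(
    {"untreated": blank + 0.001, "ari": blank + 0.01 * (triton - blank), "ola": blank + 0.001},
    control="untreated",
    noise_sigma=0.002,
    replicates=6,
    parallels=2,           # each sample loaded in two parallel wells
    blank_mean=blank,
    positive_mean=triton,
    seed=11,
)
per_sample, per_group = haemolysis_table(plate)
print(per_group.round(3).to_string(index=False))

samples = per_sample[per_sample["role"].isin(["sample", "untreated_control"])]
groups = groups_from_frame(
    samples.rename(columns={"haemolysis_pct": "value"}), control="untreated"
)
res = dunnett_vs_control(groups, seed=0)
for c in res.comparisons:
    print(f"{c.label} vs untreated: diff {c.mean_diff:+.2f} pts, "
          f"adjusted p = {c.p_adjusted:.4f} {c.stars}")

# Only the haemolysing treatment should come out Dunnett-significant;
# blanks anchor 0% and the Triton control anchors 100% exactly.
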