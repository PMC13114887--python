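#!/usr/bin/env python
"""Significance machinery over the screening dataset.

Runs the donor x treatment interaction screen that licenses pooling across
donors, the one-way ANOVA across irradiated arms, and Tukey HSD comparisons
of every substance arm against the irradiated control; writes the tidy
comparison table under results/.
"""

from pathlib import Path

from cbmn_screen import donor_interaction_screen, one_way_anova, read_scoring_table, records_to_frame, tukey_hsd

root = Path(__file__).resolve().parents[1] / "results"
records = read_scoring_table(root / "synthetic" / "screening.csv")

screen = donor_interaction_screen(records)
print(screen.message)

df = records_to_frame(records)
irr = df[df.dose_mGy > 0].copy()
irr["arm"] = irr["substance"] + "|" + irr["timing"]
groups = {arm: g["freq_per_500"].tolist() for arm, g in irr.groupby("arm")}
anova = one_way_anova(groups)
print(f"ANOVA across {len(groups)} irradiated arms: "
      f"F({anova.df_between},{anova.df_within}) = {anova.f_statistic:.2f}, p = {anova.p_value:.3g}")

table = tukey_hsd(groups, against="control|none")
frame = table.to_frame().sort_values("adjusted_p")
frame.to_csv(root / "comparisons.csv", index=False)
n_sig = (frame["significant_at"] != "ns").sum()
print(f"Tukey HSD vs irradiated control: {n_sig}/{len(frame)} arms significant; "
      f"strongest pairs:")
print(frame.head(5).to_string(index=False))
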