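#!/usr/bin/env python
"""Score the screening panel: MP, equivalent dose, DRF, tier per arm.

Scores every substance x timing arm of the synthetic screening dataset
against the irradiated control using the published inverse curve, writes the
tidy endpoint table and the rendered report, and checks the recovered
endpoints of the strongest protector against the generator's truth.
"""

import json
from pathlib import Path

from cbmn_screen import CalibrationCurve, read_scoring_table, score_screening
from cbmn_screen.protection import results_to_frame
from cbmn_screen.report import make_report

root = Path(__file__).resolve().parents[1] / "results"
records = read_scoring_table(root / "synthetic" / "screening.csv")
curve = CalibrationCurve.from_json(root / "curve_published.json")
truth = json.loads((root / "synthetic" / "truth.json").read_text())

results = score_screening(records, curve, truth["nominal_screen_dose"])
results_to_frame(results).to_csv(root / "protection_results.csv", index=False)
(root / "screening_report.md").write_text(make_report(results, {"curve": curve, "seed": truth["seed"]}))

by_arm = {(r.substance, r.timing): r for r in results}
for timing in ("pre", "post"):
    r = by_arm[("rosmarinic_acid", timing)]
    f = truth["effects"]["rosmarinic_acid"][timing]
    print(f"rosmarinic_acid {timing:4s}: MP {r.display_mp:3d}% (truth {100 * f:.0f}%), "
          f"DRF {r.display_drf}, equiv {r.display_equiv_gy:.2f} Gy, tier {r.tier}")
print(f"scored {len(results)} arms -> protection_results.csv, screening_report.md")
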