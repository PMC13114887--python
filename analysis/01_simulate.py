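#!/usr/bin/env python
"""Generate the synthetic screening study.

Emulates the study design — 6 donors x 5 independent experiments, a 20-dose
gamma calibration schedule (0-16,362 mGy), and a 2 Gy screening arm with the
29-substance panel given pre or post exposure — and writes the scoring
tables plus the ground-truth effects map under results/synthetic/.
"""

import argparse
from pathlib import Path

from cbmn_screen import SyntheticConfig, simulate_calibration_dataset, simulate_screening_experiment, write_scoring_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

out = Path(__file__).resolve().parents[1] / "results" / "synthetic"
out.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(seed=args.seed)
calibration = simulate_calibration_dataset(cfg)
screening = simulate_screening_experiment(cfg)
write_scoring_table(calibration, out / "calibration.csv")
write_scoring_table(screening, out / "screening.csv")
cfg.write_truth(out / "truth.json")

print(f"calibration: {len(calibration)} cultures over {len(cfg.calibration_doses)} doses")
print(f"screening:   {len(screening)} cultures over {len(cfg.effects)} substances x pre/post")
print(f"wrote scoring tables and truth.json to {out}")
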