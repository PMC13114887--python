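#!/usr/bin/env python
"""Fit the dose-response calibration line and compare with the published one.

Fits MN/500 BC on dose by OLS over the synthetic 20-dose schedule, reports
the inverse dosimetry equation D = a + b y and its reliability (100 R^2),
and writes both the fitted and the published curve as JSON under results/.
"""

from pathlib import Path

from cbmn_screen import fit_linear, from_inverse_coefficients, read_scoring_table

root = Path(__file__).resolve().parents[1] / "results"
records = read_scoring_table(root / "synthetic" / "calibration.csv")
curve = fit_linear([(r.dose_mGy, r.frequency_per_500) for r in records])
curve.to_json(root / "curve_fitted.json")

published = from_inverse_coefficients(-429.54, 64.37)
published.to_json(root / "curve_published.json")

print(f"fitted inverse line:    D = {curve.a:8.2f} + {curve.b:6.2f} y   "
      f"(reliability {curve.percent_reliability:.2f}%, n = {curve.n_points})")
print(f"published inverse line: D = {published.a:8.2f} + {published.b:6.2f} y")
print("Screening endpoints downstream use the published line: the observed 2 Gy")
print("control (26 MN/500 BC) is not on the calibration line, so the curve is an")
print("explicit input rather than a refit of screening controls.")
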