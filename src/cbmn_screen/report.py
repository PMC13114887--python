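"""Human-readable markdown run report.

Rendering is deterministic: numbers are shown with the display conventions
of :mod:`cbmn_screen.protection` (MP to the integer percent, DRF to one
decimal, equivalent dose in Gy truncated to two decimals); the raw values
stay in the CSV outputs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .calibration import CalibrationCurve
from .protection import ProtectionResult
from .stats import InteractionScreen


def make_report(
    results: Sequence[ProtectionResult],
    diagnostics: Mapping | None = None,
) -> str:
    """Render screening results and run diagnostics as markdown."""
    diagnostics = dict(diagnostics or {})
    lines: list[str] = ["# CBMN radioprotector screening report", ""]

    seed = diagnostics.get("seed")
    if seed is not None:
        lines += [f"Seed: {seed}", ""]

    curve: CalibrationCurve | None = diagnostics.get("curve")
    if curve is not None:
        lines += ["## Calibration curve", ""]
        lines += [f"Inverse dosimetry equation: D = {curve.a:.2f} + {curve.b:.2f} y  (mGy; y in MN/500 BC)"]
        lines += [f"Forward line: y = {curve.c0:.4f} + {curve.c1:.6f} D; source: {curve.source}"]
        if curve.percent_reliability is not None:
            lines += [f"Reliability: {curve.percent_reliability:.2f}% (n = {curve.n_points} points)"]
        lines += [""]

    screen: InteractionScreen | None = diagnostics.get("interaction_screen")
    if screen is not None:
        lines += ["## Donor pooling screen", "", screen.message, ""]

    cbpi_flags = diagnostics.get("cbpi_flags")
    if cbpi_flags is not None:
        n_fail = sum(1 for f in cbpi_flags if f == "fail")
        lines += [
            "## Culture quality (CBPI)",
            "",
            f"{len(cbpi_flags)} conditions checked; {n_fail} outside the 1.3-1.7 window.",
            "",
        ]

    lines += ["## Protection endpoints", ""]
    if not results:
        lines += ["No substances scored.", ""]
    else:
        lines += [
            "| substance | timing | MN/500 BC | MP (%) | MP net of DMSO (%) | equiv. dose (Gy) | DRF | p vs CI | tier |",
            "|---|---|---|---|---|---|---|---|---|",
        ]
        for r in sorted(results, key=lambda r: (r.timing, -r.mp_percent)):
            mp_norm = "" if r.mp_percent_dmso_normalized is None else f"{r.mp_percent_dmso_normalized:.0f}"
            p = "" if r.p_vs_irradiated_control is None else f"{r.p_vs_irradiated_control:.2g}"
            lines.append(
                f"| {r.substance} | {r.timing} | {r.fmn_treated_irradiated.value:.1f} "
                f"| {r.display_mp} | {mp_norm} | {r.display_equiv_gy:.2f} | {r.display_drf} "
                f"| {p} | {r.tier} |"
            )
        lines += [""]
    return "\n".join(lines) + "\n"
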