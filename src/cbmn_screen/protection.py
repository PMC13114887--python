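"""Substance-level screening endpoints: MP, equivalent dose, DRF, tiers.

For a substance given at the nominal exposure (2 Gy here) the two endpoints
are

    MP (%) = (FMN_control_irr - FMN_treated_irr) / FMN_control_irr * 100

the magnitude of protection (percent reduction in MN frequency relative to
the irradiated control), and the dose reduction factor

    DRF = D_nominal / D_equiv,   D_equiv = a + b * FMN_treated_irr,

the ratio of the delivered dose to the gamma dose that would produce the
treated arm's MN frequency in untreated cells, read off the inverse
calibration curve.  DRF > 1 indicates protection.  The DRF numerator is the
nominal delivered dose: this reading reproduces the published endpoint set
(MP 58% together with DRF 7.2 and an equivalent dose of 0.27 Gy for the top
protector) whereas using the control arm's own interpolated dose would not.

Lipophilic substances dissolved in DMSO are additionally reported net of the
solvent's own protection (MP_substance = MP_total - MP_dmso).

Display conventions (raw values are never rounded internally): MP to the
nearest integer percent, DRF to one decimal, equivalent dose in Gy truncated
(not rounded) to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calibration import CalibrationCurve, DoseEstimate, estimate_dose
from .errors import DegenerateVarianceError, MissingGroupError, PipelineError, ValidationError
from .mn_data import CultureRecord, FrequencyPer500BC, records_to_frame
from .stats import ALPHA_TIERS, tukey_hsd

TIER_PROTECTOR_STRONG = "protector_strong"
TIER_PROTECTOR_MODERATE = "protector_moderate"
TIER_NOT_SIGNIFICANT = "not_significant"
TIER_RADIOSENSITIZER = "radiosensitizer"

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class ProtectionResult:
    """Screening endpoints for one substance in one timing arm."""

    substance: str
    timing: str
    fmn_control_irradiated: FrequencyPer500BC
    fmn_treated_irradiated: FrequencyPer500BC
    mp_percent: float
    equiv_dose: DoseEstimate
    drf: float  # may be math.inf when the equivalent dose clamps to 0
    nominal_dose_mGy: float
    p_vs_irradiated_control: float | None
    tier: str
    solvent: str = "aqueous"
    mp_percent_dmso_normalized: float | None = None
    complete_protection: bool = False

    @property
    def display_mp(self) -> int:
        return display_mp(self.mp_percent)

    @property
    def display_drf(self) -> str:
        return "complete protection" if self.complete_protection else f"{self.drf:.1f}"

    @property
    def display_equiv_gy(self) -> float:
        return display_equiv_gy(self.equiv_dose.dose_mGy)


def display_mp(mp_percent: float) -> int:
    """MP rounded half-up to the nearest integer percent."""
    return int(math.floor(mp_percent + 0.5))


def display_drf(drf: float) -> float:
    """DRF rounded to one decimal."""
    return round(drf, 1)


def display_equiv_gy(dose_mGy: float) -> float:
    """Equivalent dose in Gy, truncated (not rounded) to two decimals."""
    return math.floor(dose_mGy / 10.0) / 100.0


def magnitude_of_protection(fmn_control_irr: float, fmn_treated_irr: float) -> float:
    """Percent reduction of the treated arm relative to the irradiated control.

    Returns the unrounded value; may be negative (radiosensitization) and is
    at most 100.
    """
    c = float(fmn_control_irr)
    t = float(fmn_treated_irr)
    if c <= 0:
        raise ValidationError("MP undefined: irradiated-control frequency must be positive")
    if t < 0:
        raise ValidationError("treated frequency must be non-negative")
    return (c - t) / c * 100.0


def dose_reduction_factor(
    curve: CalibrationCurve,
    nominal_dose_mGy: float,
    fmn_treated_irr: float,
) -> tuple[DoseEstimate, float]:
    """Equivalent dose of the treated arm and the dose reduction factor.

    DRF = nominal delivered dose / equivalent dose.  When the equivalent
    dose clamps to 0 (frequency below the curve's zero-dose intercept) the
    DRF is reported as +inf: complete protection at curve resolution.
    """
    if nominal_dose_mGy <= 0:
        raise ValidationError(f"nominal dose must be positive, got {nominal_dose_mGy}")
    equiv = estimate_dose(curve, fmn_treated_irr)
    drf = math.inf if equiv.dose_mGy == 0.0 else nominal_dose_mGy / equiv.dose_mGy
    return equiv, drf


def dmso_normalize(
    mp_total_percent: float,
    mp_dmso_percent: float,
    timing_total: str | None = None,
    timing_dmso: str | None = None,
) -> float:
    """Subtract the solvent-only MP from a compound-plus-DMSO MP.

    Both values must come from the same timing arm when timings are given.
    Negative results are legitimate (net radiosensitizing after solvent
    correction).
    """
    if timing_total is not None and timing_dmso is not None and timing_total != timing_dmso:
        raise ValidationError(
            f"DMSO normalization requires matching timing arms, got {timing_total!r} vs {timing_dmso!r}"
        )
    return mp_total_percent - mp_dmso_percent


def assess_genotoxicity(
    fmn_treated_unirradiated: float,
    fmn_control_unirradiated: float,
    p_value: float,
) -> str:
    """Genotoxicity call for a substance in the absence of irradiation.

    ``"genotoxic"`` iff the treated arm exceeds the untreated control and the
    (two-tailed) comparison is significant at 0.05.
    """
    increase = float(fmn_treated_unirradiated) > float(fmn_control_unirradiated)
    return "genotoxic" if (increase and p_value < 0.05) else "not_genotoxic"


def classify_substance(p_value: float, direction: float) -> str:
    """Protection tier from the control comparison.

    ``direction`` is the sign of (treated - control): negative means the
    substance lowered the MN frequency.  Tiers follow the 0.001/0.01 marks
    used for screening figures: a significant decrease at p < 0.001 is a
    strong protector, at p < 0.01 a moderate one; a significant increase at
    p < 0.01 flags a radiosensitizer; anything else is not significant.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValidationError(f"p-value must be in [0, 1], got {p_value}")
    if direction < 0:
        if p_value < 0.001:
            return TIER_PROTECTOR_STRONG
        if p_value < 0.01:
            return TIER_PROTECTOR_MODERATE
        return TIER_NOT_SIGNIFICANT
    if direction > 0 and p_value < 0.01:
        return TIER_RADIOSENSITIZER
    return TIER_NOT_SIGNIFICANT


def score_screening(
    records: Sequence[CultureRecord],
    curve: CalibrationCurve,
    nominal_dose_mGy: float,
    control_label: str = CONTROL_LABEL,
    dmso_label: str = "dmso",
    alpha_levels: Sequence[float] = ALPHA_TIERS,
) -> list[ProtectionResult]:
    """Score every substance x timing arm against the irradiated control.

    Expects per-culture records including an irradiated control arm
    (``substance == control_label`` at the nominal dose).  Group means over
    cultures give the condition-level frequencies entering MP and DRF; the
    p-value per arm is the Tukey-HSD adjusted p of the comparison with the
    irradiated control, within the family of all irradiated arms.  When a
    solvent-only DMSO arm is present, substances recorded with
    ``solvent == "dmso"`` also get a solvent-normalized MP.
    """
    df = records_to_frame(list(records))
    irr = df[df["dose_mGy"] == nominal_dose_mGy]
    ctrl = irr[irr["substance"] == control_label]
    if ctrl.empty:
        raise PipelineError(
            f"no irradiated control arm (substance {control_label!r} at {nominal_dose_mGy} mGy) in data"
        )

    def arm_freq(sub: pd.DataFrame) -> FrequencyPer500BC:
        vals = sub["freq_per_500"]
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else None
        return FrequencyPer500BC(value=float(vals.mean()), se=se)

    fmn_control = arm_freq(ctrl)

    # family of irradiated arms for the Tukey comparison
    groups: dict[str, list[float]] = {control_label: ctrl["freq_per_500"].tolist()}
    arms: list[tuple[str, str, pd.DataFrame]] = []
    for (sub, timing), grp in irr[irr["substance"] != control_label].groupby(["substance", "timing"]):
        key = f"{sub}|{timing}"
        groups[key] = grp["freq_per_500"].tolist()
        arms.append((sub, timing, grp))
    if not arms:
        raise MissingGroupError("no treated irradiated arms to score")

    # significance is skipped (p = None) for unreplicated or zero-variance
    # inputs such as condition-level worked examples
    tukey = None
    if all(len(v) >= 2 for v in groups.values()):
        try:
            tukey = tukey_hsd(groups, alpha_levels=alpha_levels, against=control_label)
        except DegenerateVarianceError:
            tukey = None

    # solvent-only MP per timing, for DMSO normalization
    dmso_mp: dict[str, float] = {}
    for sub, timing, grp in arms:
        if sub == dmso_label:
            dmso_mp[timing] = magnitude_of_protection(fmn_control.value, arm_freq(grp).value)

    results: list[ProtectionResult] = []
    for sub, timing, grp in arms:
        fmn_treated = arm_freq(grp)
        mp = magnitude_of_protection(fmn_control.value, fmn_treated.value)
        equiv, drf = dose_reduction_factor(curve, nominal_dose_mGy, fmn_treated.value)
        if tukey is not None:
            comp = tukey.lookup(control_label, f"{sub}|{timing}")
            p = comp.adjusted_p
            tier = classify_substance(p, fmn_treated.value - fmn_control.value)
        else:
            p, tier = None, TIER_NOT_SIGNIFICANT
        solvent = grp["solvent"].mode().iat[0]
        mp_norm = None
        if solvent == "dmso" and sub != dmso_label and timing in dmso_mp:
            mp_norm = dmso_normalize(mp, dmso_mp[timing], timing, timing)
        results.append(
            ProtectionResult(
                substance=sub,
                timing=timing,
                fmn_control_irradiated=fmn_control,
                fmn_treated_irradiated=fmn_treated,
                mp_percent=mp,
                equiv_dose=equiv,
                drf=drf,
                nominal_dose_mGy=nominal_dose_mGy,
                p_vs_irradiated_control=p,
                tier=tier,
                solvent=solvent,
                mp_percent_dmso_normalized=mp_norm,
                complete_protection=equiv.clamped,
            )
        )
    return results


def results_to_frame(results: Sequence[ProtectionResult]) -> pd.DataFrame:
    """Tidy results table with raw (unrounded) values."""
    return pd.DataFrame(
        [
            {
                "substance": r.substance,
                "timing": r.timing,
                "solvent": r.solvent,
                "fmn_control_irr": r.fmn_control_irradiated.value,
                "fmn_treated_irr": r.fmn_treated_irradiated.value,
                "mp_percent": r.mp_percent,
                "mp_percent_dmso_normalized": r.mp_percent_dmso_normalized,
                "equiv_dose_mGy": r.equiv_dose.dose_mGy,
                "equiv_dose_clamped": r.equiv_dose.clamped,
                "drf": r.drf,
                "nominal_dose_mGy": r.nominal_dose_mGy,
                "p_vs_irradiated_control": r.p_vs_irradiated_control,
                "tier": r.tier,
            }
            for r in results
        ]
    )
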