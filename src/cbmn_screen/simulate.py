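"""Synthetic CBMN dataset generator matching the screening study design.

The generator emulates the design the analysis assumes: 6 donors, 5
independent experiments (culture days) per condition, 500 BC scored per
culture, a 20-point gamma calibration schedule spanning 0-16,362 mGy, and a
2 Gy screening arm in which each of 29 substances is given at 25 uM either
immediately before or immediately after exposure.

Counts per culture are Poisson (optionally negative-binomial with variance
mean*(1 + dispersion)) around an arm mean.  Protection acts multiplicatively
on the irradiated-control mean: an effect f in (-inf, 1] gives a treated
mean of (1 - f) * irradiated_control_mean, so the configured f and the
expected magnitude of protection coincide exactly (f < 0 encodes
radiosensitizers).  Donor heterogeneity is a mean-one multiplicative
log-normal factor shared by all of a donor's cultures.  DMSO adds its own
protection fraction in the pre-exposure arm only.

One seed governs the entire dataset; the same config reproduces it
byte-identically.  The ground-truth effects map is written alongside the
data so downstream checks never re-derive truth from outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .mn_data import CultureRecord

#: inverse slope of the published dosimetry line, MN/500 BC per mGy
DEFAULT_SLOPE = 1.0 / 64.37

#: calibration schedule: sham plus 19 log-spaced doses from 1.3 cGy to 16,362 mGy
DEFAULT_CALIBRATION_DOSES = tuple(
    [0.0] + [float(round(d)) for d in np.geomspace(13.0, 16362.0, 19)]
)


def default_effects() -> dict[str, dict[str, float]]:
    """Protection-fraction map for the 29-substance screening panel.

    The handful of substances with published endpoints carry those effects
    (rosmarinic acid 0.58 pre / 0.08 post; amifostine 0.38 pre; vitamins E
    and C 0.50 and 0.38 pre; long-chain procyanidins strongest post;
    quercetin and zoledronic acid radiosensitizing).  The remaining panel
    slots are synthetic placeholders spanning the same range, fixed so the
    default dataset is reproducible.
    """
    eff: dict[str, dict[str, float]] = {
        "rosmarinic_acid": {"pre": 0.58, "post": 0.08},
        "amifostine": {"pre": 0.38, "post": 0.10},
        "vitamin_e": {"pre": 0.50, "post": 0.25},
        "vitamin_c": {"pre": 0.38, "post": 0.12},
        "procyanidin_long": {"pre": 0.30, "post": 0.47},
        "quercetin": {"pre": -0.20, "post": 0.05},
        "zoledronic_acid": {"pre": -0.35, "post": -0.10},
    }
    spread = [0.45, 0.40, 0.35, 0.32, 0.28, 0.25, 0.22, 0.20, 0.18, 0.15, 0.12,
              0.10, 0.08, 0.05, 0.03, 0.00, -0.02, -0.05, 0.33, 0.27, 0.17, 0.07]
    for i, f in enumerate(spread, start=8):
        eff[f"panel_{i:02d}"] = {"pre": f, "post": round(f * 0.4, 3)}
    return eff


def default_solvents() -> dict[str, str]:
    """Solvent per substance; lipophilic panel members are DMSO-dissolved."""
    dmso = {"vitamin_e", "procyanidin_long", "quercetin",
            "panel_19", "panel_20", "panel_26", "panel_27"}
    return {s: ("dmso" if s in dmso else "aqueous") for s in default_effects()}


@dataclass
class SyntheticConfig:
    """Full generative model for a synthetic CBMN screening study."""

    baseline_freq: float = 10.0          # MN/500 BC at zero dose (0.02 MN/BC)
    slope: float = DEFAULT_SLOPE         # MN/500 BC per mGy
    dispersion: float = 0.0              # variance = mean * (1 + dispersion)
    donor_sd: float = 0.05               # log-scale SD of the donor factor
    n_donors: int = 6
    n_experiments: int = 5
    n_bc_scored: int = 500
    calibration_doses: tuple = DEFAULT_CALIBRATION_DOSES
    nominal_screen_dose: float = 2000.0  # mGy
    irradiated_control_mean: float = 26.0  # MN/500 BC
    effects: dict = field(default_factory=default_effects)
    solvents: dict = field(default_factory=default_solvents)
    dmso_offset: float = 0.10            # solvent protection fraction, pre arm only
    cbpi_target: float = 1.65
    include_cbpi: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_freq < 0 or self.slope < 0:
            raise ValidationError("baseline and slope must be non-negative")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        if self.donor_sd < 0:
            raise ValidationError("donor_sd must be non-negative")
        if self.n_donors < 1 or self.n_experiments < 1:
            raise ValidationError("need at least one donor and one experiment")
        if not 1.0 <= self.cbpi_target <= 3.0:
            raise ValidationError(f"CBPI target must lie in [1, 3], got {self.cbpi_target}")
        for sub, by_timing in self.effects.items():
            for timing, f in by_timing.items():
                if timing not in ("pre", "post"):
                    raise ValidationError(f"effect for {sub!r} names unknown timing {timing!r}")
                if f > 1.0:
                    raise ValidationError(f"effect for {sub!r}/{timing} exceeds 1 (negative mean)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "calibration_doses" in d:
            d["calibration_doses"] = tuple(float(x) for x in d["calibration_doses"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(doc or {})

    def truth(self) -> dict:
        """Ground-truth parameters, for writing alongside generated data."""
        doc = asdict(self)
        doc["calibration_doses"] = list(self.calibration_doses)
        return doc

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth(), indent=2) + "\n", encoding="utf-8")


def _donor_factors(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative log-normal donor effects."""
    if config.donor_sd == 0:
        return np.ones(config.n_donors)
    s = config.donor_sd
    return np.exp(rng.normal(-0.5 * s * s, s, config.n_donors))


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Poisson count, or negative binomial with variance mean*(1+dispersion).

    The NB is parameterized as (r, p) = (mean/dispersion, 1/(1+dispersion)),
    which degenerates continuously to Poisson as dispersion -> 0.
    """
    if mean < 0:
        raise ValidationError(f"negative arm mean {mean}; check effects and offsets")
    if mean == 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return int(rng.negative_binomial(r, p))


def simulate_cbpi_tallies(
    config: SyntheticConfig,
    n_cells: int,
    rng: np.random.Generator | None = None,
) -> tuple[int, int, int]:
    """Multinomial (mono, bi, multi) tallies with expected CBPI = cbpi_target.

    With total cell count fixed, E[CBPI] = p1 + 2 p2 + 3 p3 exactly; the
    multinucleate share is capped at 5%, as in healthy lymphocyte cultures.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    target = config.cbpi_target
    p3 = min(0.05, (target - 1.0) / 2.0)
    p2 = target - 1.0 - 2.0 * p3
    p1 = 1.0 - p2 - p3
    draw = rng.multinomial(n_cells, [p1, p2, p3])
    return int(draw[0]), int(draw[1]), int(draw[2])


def _make_record(
    config: SyntheticConfig,
    rng: np.random.Generator,
    donor: int,
    exp: int,
    substance: str,
    timing: str,
    solvent: str,
    dose: float,
    mean: float,
) -> CultureRecord:
    count = _draw_count(rng, mean, config.dispersion)
    tallies = (
        simulate_cbpi_tallies(config, config.n_bc_scored * 2, rng)
        if config.include_cbpi
        else (None, None, None)
    )
    return CultureRecord(
        donor_id=f"D{donor + 1}",
        experiment_id=f"E{exp + 1}",
        substance=substance,
        timing=timing,
        solvent=solvent,
        dose_mGy=float(dose),
        n_bc_scored=config.n_bc_scored,
        mn_count=count,
        n_mono=tallies[0],
        n_bi=tallies[1],
        n_multi=tallies[2],
    )


def simulate_calibration_dataset(config: SyntheticConfig) -> list[CultureRecord]:
    """Dose-response dataset over the calibration schedule.

    One culture per dose x donor x experiment, mean
    (baseline + slope * dose) * donor_factor, recorded as untreated controls.
    """
    rng = np.random.default_rng([config.seed, 0])
    donor_factor = _donor_factors(config, rng)
    records = []
    for dose in config.calibration_doses:
        for d in range(config.n_donors):
            mean = (config.baseline_freq + config.slope * dose) * donor_factor[d]
            for e in range(config.n_experiments):
                records.append(
                    _make_record(config, rng, d, e, "control", "none", "aqueous", dose, mean)
                )
    return records


def _arm_means(config: SyntheticConfig) -> list[tuple[str, str, str, float, float]]:
    """(substance, timing, solvent, dose, mean) for every screening arm."""
    icm = config.irradiated_control_mean
    nominal = config.nominal_screen_dose
    arms = [
        ("control", "none", "aqueous", 0.0, config.baseline_freq),
        ("control", "none", "aqueous", nominal, icm),
    ]
    if any(s == "dmso" for s in config.solvents.values()) or config.dmso_offset != 0:
        arms.append(("dmso", "pre", "dmso", nominal, (1.0 - config.dmso_offset) * icm))
        arms.append(("dmso", "post", "dmso", nominal, icm))
    for sub, by_timing in config.effects.items():
        solvent = config.solvents.get(sub, "aqueous")
        for timing, f in by_timing.items():
            f_total = f + (config.dmso_offset if solvent == "dmso" and timing == "pre" else 0.0)
            mean = (1.0 - f_total) * icm
            if mean < 0:
                raise ValidationError(
                    f"arm {sub!r}/{timing} has negative mean (total effect {f_total} > 1)"
                )
            arms.append((sub, timing, solvent, nominal, mean))
    return arms


def simulate_screening_experiment(config: SyntheticConfig) -> list[CultureRecord]:
    """Screening dataset: controls, solvent arms and all substance arms.

    Arm means follow the effects map; every arm is replicated over
    n_donors x n_experiments cultures with shared donor factors.
    """
    rng = np.random.default_rng([config.seed, 1])
    donor_factor = _donor_factors(config, rng)
    records = []
    for sub, timing, solvent, dose, mean in _arm_means(config):
        for d in range(config.n_donors):
            for e in range(config.n_experiments):
                records.append(
                    _make_record(config, rng, d, e, sub, timing, solvent, dose, mean * donor_factor[d])
                )
    return records
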