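"""Micronucleus dose-response calibration and inverse dose estimation.

The dose-response of MN frequency in gamma-irradiated lymphocytes is modelled
as a straight line over the calibrated range,

    y = c0 + c1 * D          (forward: dose in mGy -> MN/500 BC)

whose exact inverse is the biological-dosimetry estimator

    D = a + b * y,   a = -c0/c1 [mGy],   b = 1/c1 [mGy per MN/500 BC].

Both parameterizations are views of the same fit and are kept consistent at
all times.  A curve may also be constructed directly from published inverse
coefficients (a, b), in which case fit diagnostics are absent.  Negative
inverse doses (frequencies below the zero-dose intercept, expected in well
protected samples) are clamped to 0 mGy and flagged.

An optional linear-quadratic fit y = c0 + c1 D + c2 D^2 is provided for
comparison with the literature; it is never used by the screening endpoints.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import NoRealDoseError, NonInvertibleCurveError, SingularDesignError, ValidationError


@dataclass
class CalibrationCurve:
    """Linear dose-response fit and its exact inverse.

    ``c0``: MN/500 BC at zero dose; ``c1``: MN/500 BC per mGy (must be > 0
    for invertibility).  ``source`` records whether the curve was fit to data
    or taken from published inverse coefficients.
    """

    c0: float
    c1: float
    n_points: int = 0
    r_squared: float | None = None
    residual_sd: float | None = None
    source: str = "fit"
    # retained calibration points, enabling bootstrap dose intervals
    doses: np.ndarray | None = field(default=None, repr=False)
    freqs: np.ndarray | None = field(default=None, repr=False)

    @property
    def invertible(self) -> bool:
        return self.c1 > 0

    @property
    def a(self) -> float:
        """Inverse intercept, mGy."""
        self._require_invertible()
        return -self.c0 / self.c1

    @property
    def b(self) -> float:
        """Inverse slope, mGy per MN/500 BC."""
        self._require_invertible()
        return 1.0 / self.c1

    @property
    def percent_reliability(self) -> float | None:
        """R^2 expressed as a percentage, the convention of dosimetry reports."""
        return None if self.r_squared is None else 100.0 * self.r_squared

    def forward(self, dose_mGy: float | np.ndarray) -> float | np.ndarray:
        """Expected MN/500 BC at a given dose."""
        return self.c0 + self.c1 * np.asarray(dose_mGy, dtype=float)[()]

    def _require_invertible(self) -> None:
        if not self.invertible:
            raise NonInvertibleCurveError(
                f"curve with slope c1={self.c1} is not invertible; dose estimation disabled"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "forward": {"c0": self.c0, "c1": self.c1},
            "inverse": {"a": self.a, "b": self.b} if self.invertible else None,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "percent_reliability": self.percent_reliability,
            "residual_sd": self.residual_sd,
            "source": self.source,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        fwd = doc["forward"]
        return cls(
            c0=float(fwd["c0"]),
            c1=float(fwd["c1"]),
            n_points=int(doc.get("n_points") or 0),
            r_squared=doc.get("r_squared"),
            residual_sd=doc.get("residual_sd"),
            source=doc.get("source", "fit"),
        )


@dataclass(frozen=True)
class DoseEstimate:
    """A dose read off the inverse calibration curve.

    ``clamped`` is true iff the raw inverse value was negative and the
    reported dose is 0.  The optional interval is a percentile bootstrap over
    calibration points.
    """

    dose_mGy: float
    clamped: bool = False
    ci_low_mGy: float | None = None
    ci_high_mGy: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low_mGy is not None and self.ci_high_mGy is not None:
            if not (self.ci_low_mGy <= self.dose_mGy <= self.ci_high_mGy):
                raise ValidationError("bootstrap interval must bracket the dose estimate")


def fit_linear(
    points: Sequence[tuple[float, float]],
    poisson_weights: bool = False,
) -> CalibrationCurve:
    """Least-squares fit of MN/500 BC on dose.

    ``points`` are (dose_mGy, frequency) pairs; unweighted OLS by default.
    ``poisson_weights=True`` switches to weighted least squares with weights
    proportional to 1/mean (variance of a Poisson count equals its mean),
    using the unweighted fitted means.  Requires at least three distinct
    doses.  If the fitted slope is not positive the curve is returned with
    inversion disabled and a warning is issued.
    """
    doses = np.asarray([p[0] for p in points], dtype=float)
    freqs = np.asarray([float(p[1]) for p in points], dtype=float)
    if np.any(doses < 0):
        raise ValidationError("calibration doses must be non-negative")
    if len(np.unique(doses)) < 3:
        raise SingularDesignError("calibration requires >= 3 distinct dose points")

    res = stats.linregress(doses, freqs)
    c0, c1 = float(res.intercept), float(res.slope)
    weights = None
    if poisson_weights:
        weights = 1.0 / np.maximum(c0 + c1 * doses, 0.5)
        X = np.vstack([np.ones_like(doses), doses]).T
        W = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(X * W[:, None], freqs * W, rcond=None)
        c0, c1 = float(coef[0]), float(coef[1])

    resid = freqs - (c0 + c1 * doses)
    dof = len(doses) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    if weights is None:
        r2 = float(res.rvalue**2)
    else:
        wmean = np.average(freqs, weights=weights)
        r2 = 1.0 - float(np.sum(weights * resid**2) / np.sum(weights * (freqs - wmean) ** 2))
    curve = CalibrationCurve(
        c0=c0,
        c1=c1,
        n_points=len(doses),
        r_squared=r2,
        residual_sd=residual_sd,
        doses=doses,
        freqs=freqs,
    )
    if not curve.invertible:
        warnings.warn("fitted slope is not positive; dose estimation disabled for this curve")
    return curve


def from_inverse_coefficients(a: float, b: float) -> CalibrationCurve:
    """Build a curve from a published inverse equation D = a + b*y.

    No refit takes place; diagnostics are marked absent and the source is
    recorded as "published".
    """
    if b <= 0:
        raise NonInvertibleCurveError(f"inverse slope b must be positive, got {b}")
    return CalibrationCurve(c0=-a / b, c1=1.0 / b, source="published")


def estimate_dose(
    curve: CalibrationCurve,
    y: float,
    ci: bool = False,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> DoseEstimate:
    """Dose equivalent to an observed MN frequency: D = a + b*y.

    Negative raw doses are clamped to 0 with ``clamped=True`` (sub-baseline
    frequencies are expected in protected samples).  With ``ci=True`` and a
    fitted curve, a seeded percentile bootstrap over calibration points gives
    the interval; bootstrap doses are clamped the same way.
    """
    curve._require_invertible()
    y = float(y)
    raw = curve.a + curve.b * y
    clamped = raw < 0
    if clamped:
        warnings.warn(f"inverse dose {raw:.1f} mGy is negative; clamped to 0 (frequency below intercept)")
    dose = 0.0 if clamped else raw

    lo = hi = None
    if ci:
        if curve.doses is None or curve.freqs is None:
            raise ValidationError("bootstrap interval requires a curve fitted to retained data")
        rng = np.random.default_rng(seed)
        n = len(curve.doses)
        sims = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            d, f = curve.doses[idx], curve.freqs[idx]
            if len(np.unique(d)) < 3:
                sims[i] = dose
                continue
            r = stats.linregress(d, f)
            sims[i] = max(0.0, (y - r.intercept) / r.slope) if r.slope > 0 else dose
        alpha = 1 - ci_level
        lo = float(np.quantile(sims, alpha / 2))
        hi = float(np.quantile(sims, 1 - alpha / 2))
        lo, hi = min(lo, dose), max(hi, dose)
    return DoseEstimate(dose_mGy=dose, clamped=clamped, ci_low_mGy=lo, ci_high_mGy=hi)


@dataclass
class QuadraticCurve:
    """Linear-quadratic fit y = c0 + c1 D + c2 D^2, for comparison only."""

    c0: float
    c1: float
    c2: float
    n_points: int = 0
    r_squared: float | None = None

    def forward(self, dose_mGy: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(dose_mGy, dtype=float)
        return (self.c0 + self.c1 * d + self.c2 * d**2)[()]

    def inverse(self, y: float) -> float:
        """Smallest non-negative dose with forward(D) = y."""
        y = float(y)
        if abs(self.c2) < 1e-300:
            if self.c1 <= 0:
                raise NonInvertibleCurveError("degenerate quadratic with non-positive slope")
            d = (y - self.c0) / self.c1
            if d < 0:
                raise NoRealDoseError(f"no non-negative dose yields frequency {y}")
            return d
        disc = self.c1**2 - 4 * self.c2 * (self.c0 - y)
        if disc < 0:
            raise NoRealDoseError(f"no real dose yields frequency {y}")
        roots = sorted(((-self.c1 + s * math.sqrt(disc)) / (2 * self.c2) for s in (1.0, -1.0)))
        for r in roots:
            if r >= -1e-9:
                return max(r, 0.0)
        raise NoRealDoseError(f"no non-negative dose yields frequency {y}")


def fit_linear_quadratic(points: Sequence[tuple[float, float]]) -> QuadraticCurve:
    """Least-squares linear-quadratic fit; reduces to the line when c2 = 0."""
    doses = np.asarray([p[0] for p in points], dtype=float)
    freqs = np.asarray([float(p[1]) for p in points], dtype=float)
    if len(np.unique(doses)) < 3:
        raise SingularDesignError("linear-quadratic fit requires >= 3 distinct dose points")
    c2, c1, c0 = np.polyfit(doses, freqs, 2)
    fitted = c0 + c1 * doses + c2 * doses**2
    ss_res = float(np.sum((freqs - fitted) ** 2))
    ss_tot = float(np.sum((freqs - freqs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticCurve(c0=float(c0), c1=float(c1), c2=float(c2), n_points=len(doses), r_squared=r2)
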