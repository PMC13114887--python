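"""Significance machinery: one-way ANOVA, Tukey HSD, donor-pooling screen.

Analyses run on the MN/500 BC scale.  Tukey's honestly significant
difference test adjusts pairwise comparisons via the studentized range
distribution; unbalanced groups use the Tukey-Kramer harmonic form

    q_ab = |mean_a - mean_b| / sqrt(MS_within/2 * (1/n_a + 1/n_b)).

The donor screen is a fixed-factor two-way ANOVA with a donor x treatment
interaction term; pooling across donors is licensed when the interaction is
not significant at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, ValidationError
from .mn_data import CultureRecord, records_to_frame

ALPHA_TIERS = (0.001, 0.01, 0.05)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    ms_within: float


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b
    q_statistic: float
    adjusted_p: float
    significant_at: str  # "0.001", "0.01", "0.05" or "ns"


@dataclass(frozen=True)
class TukeyTable:
    comparisons: tuple[TukeyComparison, ...]
    k_groups: int
    df_within: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "mean_diff": c.mean_diff,
                    "q": c.q_statistic,
                    "adjusted_p": c.adjusted_p,
                    "significant_at": c.significant_at,
                }
                for c in self.comparisons
            ]
        )

    def lookup(self, group_a: str, group_b: str) -> TukeyComparison:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {group_a, group_b}:
                return c
        raise KeyError(f"no comparison between {group_a!r} and {group_b!r}")


def _check_groups(
    groups: Mapping[str, Sequence[float]], sqrt_transform: bool = False
) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if len(v) < 2:
            raise ValidationError(f"group {k!r} needs >= 2 observations")
        if sqrt_transform and np.any(v < 0):
            raise ValidationError(f"group {k!r} has negative values; sqrt transform undefined")
    if sqrt_transform:
        arrs = {k: np.sqrt(v) for k, v in arrs.items()}
    return arrs


def _decomposition(arrs: Mapping[str, np.ndarray]) -> tuple[float, float, int, int]:
    """Classical between/within sums of squares and degrees of freedom."""
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in arrs.values())
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrs.values())
    dfb = len(arrs) - 1
    dfw = len(allv) - len(arrs)
    return float(ssb), ssw, dfb, dfw


def one_way_anova(
    groups: Mapping[str, Sequence[float]], sqrt_transform: bool = False
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with p from the F(df_between, df_within)
    distribution.  Zero within-group variance everywhere is degenerate.
    ``sqrt_transform`` analyzes sqrt(frequency), a variance-stabilizing
    option for count data; group means are reported on the analyzed scale.
    """
    arrs = _check_groups(groups, sqrt_transform)
    ssb, ssw, dfb, dfw = _decomposition(arrs)
    if ssw <= 0:
        raise DegenerateVarianceError("zero within-group variance in every group; F undefined")
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_statistic=float(f),
        df_between=dfb,
        df_within=dfw,
        p_value=p,
        group_means={k: float(v.mean()) for k, v in arrs.items()},
        ms_within=ssw / dfw,
    )


def significance_tier(p: float, alpha_levels: Sequence[float] = ALPHA_TIERS) -> str:
    """Strictest alpha tier at which p is significant, or "ns"."""
    for alpha in sorted(alpha_levels):
        if p < alpha:
            return f"{alpha:g}"
    return "ns"


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha_levels: Sequence[float] = ALPHA_TIERS,
    against: str | None = None,
    sqrt_transform: bool = False,
) -> TukeyTable:
    """Tukey HSD pairwise comparisons with studentized-range adjusted p.

    ``against`` restricts comparisons to pairs involving one reference group
    (e.g. the irradiated control), which keeps large screening runs cheap;
    the studentized-range parameters (k, df_within) still reflect the full
    family of groups.
    """
    arrs = _check_groups(groups, sqrt_transform)
    anova = one_way_anova(groups, sqrt_transform)
    k = len(arrs)
    dfw = anova.df_within
    msw = anova.ms_within

    if against is not None and against not in arrs:
        raise ValidationError(f"reference group {against!r} not among groups")
    pairs = [
        (a, b)
        for a, b in combinations(arrs, 2)
        if against is None or against in (a, b)
    ]
    rows = []
    for a, b in pairs:
        va, vb = arrs[a], arrs[b]
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(msw / 2 * (1 / len(va) + 1 / len(vb)))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, dfw))
        p = min(max(p, 0.0), 1.0)
        rows.append(TukeyComparison(a, b, diff, q, p, significance_tier(p, alpha_levels)))
    return TukeyTable(comparisons=tuple(rows), k_groups=k, df_within=dfw)


def studentized_range_critical(alpha: float, k: int, df: int) -> float:
    """Upper critical value q(alpha; k, df) of the studentized range."""
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


@dataclass(frozen=True)
class InteractionScreen:
    """Outcome of the donor x treatment interaction test."""

    interaction_p: float | None
    pooling_allowed: bool
    message: str
    f_statistic: float | None = None
    df: tuple[int, int] | None = None


def donor_interaction_screen(
    records: Sequence[CultureRecord] | pd.DataFrame,
    alpha: float = 0.05,
) -> InteractionScreen:
    """Test for a donor-by-treatment interaction before pooling donors.

    Fits a two-way fixed-factor ANOVA of MN/500 BC on donor, treatment and
    their interaction (treatment = substance x timing x dose).  Pooling
    across donors is allowed iff the interaction p >= alpha.  Unreplicated
    designs (no residual degrees of freedom) cannot be tested and return
    ``pooling_allowed=False`` with an advisory message.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df["donor_id"].nunique() < 2:
        return InteractionScreen(None, False, "cannot test: need >= 2 donors")
    df = df.copy()
    df["treatment"] = (
        df["substance"].astype(str) + "|" + df["timing"].astype(str) + "|" + df["dose_mGy"].astype(str)
    )
    if df["treatment"].nunique() < 2:
        return InteractionScreen(None, False, "cannot test: need >= 2 treatments")
    cell_sizes = df.groupby(["donor_id", "treatment"]).size()
    if (cell_sizes < 2).all():
        return InteractionScreen(
            None, False, "cannot test: unreplicated design leaves no residual df for the interaction"
        )

    model = ols("freq_per_500 ~ C(donor_id) * C(treatment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(donor_id):C(treatment)"]
    resid_df = float(table.loc["Residual", "df"])
    if resid_df <= 0 or not np.isfinite(inter["PR(>F)"]):
        return InteractionScreen(None, False, "cannot test: no residual degrees of freedom")
    p = float(inter["PR(>F)"])
    allowed = p >= alpha
    msg = (
        f"donor x treatment interaction p = {p:.4f}: "
        + ("pooling across donors allowed" if allowed else "pooling across donors NOT allowed")
    )
    return InteractionScreen(
        interaction_p=p,
        pooling_allowed=allowed,
        message=msg,
        f_statistic=float(inter["F"]),
        df=(int(inter["df"]), int(resid_df)),
    )
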