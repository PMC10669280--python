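"""Group-comparison statistics: ANOVA, Dunnett many-to-one, t-test.

The reporting surface mirrors how bench studies summarise plate and
flux-analyser endpoints: per-group mean ± SD, one-way ANOVA across more
than two groups, Dunnett's method comparing every treatment against a
single untreated control with familywise-error control, a plain two-group
t-test when there are only two groups, and the significance-star
convention ``* p <= 0.05, ** p <= 0.01, *** p <= 0.001, **** p <= 0.0001``.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "AnovaResult",
    "Comparison",
    "ComparisonResult",
    "star_code",
    "one_way_anova",
    "two_group_ttest",
    "dunnett_vs_control",
    "groups_from_frame",
]


@dataclass(frozen=True)
class GroupData:
    """One group's observations; flag exactly one group as the control."""

    label: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 observations")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {self.label!r} has non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class Comparison:
    """One treatment-vs-control contrast with its adjusted p and stars."""

    label: str
    mean_diff: float
    t: float
    p_unadjusted: float
    p_adjusted: float
    stars: str


@dataclass(frozen=True)
class ComparisonResult:
    anova: AnovaResult
    comparisons: tuple[Comparison, ...]
    control_label: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons])


def star_code(p: float) -> str:
    """Significance stars: ns, or * through **** for p <= 1e-1..1e-4 rungs."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def one_way_anova(groups: list[GroupData]) -> AnovaResult:
    """Classical one-way between/within variance decomposition.

    Degenerate inputs (zero within-group variance everywhere) are handled
    explicitly: equal means give F = 0, p = 1; unequal means are flagged
    degenerate with F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [g.values for g in groups]
    df_between = len(groups) - 1
    df_within = sum(g.n for g in groups) - len(groups)
    if all(np.ptp(a) == 0 for a in arrays):
        means = [a[0] for a in arrays]
        if np.ptp(means) == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(np.inf, df_between, df_within, 0.0, degenerate=True)
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(float(F), df_between, df_within, float(p))


def two_group_ttest(a: GroupData, b: GroupData, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; pooled variance by default, Welch optional.

    Returns ``(t, df, p)``.  Two zero-variance groups with equal means give
    t = 0, p = 1 rather than NaN.
    """
    if np.ptp(a.values) == 0 and np.ptp(b.values) == 0:
        df = a.n + b.n - 2
        if a.values[0] == b.values[0]:
            return 0.0, float(df), 1.0
        return float(np.inf * np.sign(a.values[0] - b.values[0])), float(df), 0.0
    res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _pooled_sd(groups: list[GroupData]) -> tuple[float, int]:
    df = sum(g.n for g in groups) - len(groups)
    ss = sum((g.n - 1) * g.values.var(ddof=1) for g in groups)
    return float(np.sqrt(ss / df)), df


def dunnett_vs_control(
    groups: list[GroupData],
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ComparisonResult:
    """Dunnett many-to-one comparison of every treatment against the control.

    Adjusted two-sided p-values come from the joint distribution of the
    comparison statistics under pooled within-group variance
    (:func:`scipy.stats.dunnett`, seeded multivariate-t integration).
    Each adjusted p is clipped to be no smaller than its unadjusted
    pooled-t p, which the joint distribution guarantees analytically but
    numerical integration can violate by a hair.
    """
    controls = [g for g in groups if g.is_control]
    if len(controls) != 1:
        raise ValueError(f"exactly one control group required, found {len(controls)}")
    control = controls[0]
    treatments = [g for g in groups if not g.is_control]
    if not treatments:
        raise ValueError("at least one treatment group required")

    anova = one_way_anova(groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = sps.dunnett(
        *[g.values for g in treatments], control=control.values, rng=rng
    )
    s, df = _pooled_sd(groups)
    comparisons = []
    for i, g in enumerate(treatments):
        diff = g.mean - control.mean
        se = s * np.sqrt(1.0 / g.n + 1.0 / control.n)
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p_un = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p_adj = max(float(res.pvalue[i]), p_un)
        comparisons.append(
            Comparison(
                label=g.label,
                mean_diff=float(diff),
                t=float(t),
                p_unadjusted=p_un,
                p_adjusted=p_adj,
                stars=star_code(p_adj),
            )
        )
    return ComparisonResult(
        anova=anova,
        comparisons=tuple(comparisons),
        control_label=control.label,
        alpha=alpha,
    )


def groups_from_frame(df: pd.DataFrame, control: str, value_col: str = "value", group_col: str = "group") -> list[GroupData]:
    """Build :class:`GroupData` objects from a long-format table."""
    labels = list(pd.unique(df[group_col]))
    if control not in labels:
        raise ValueError(f"control group {control!r} not present in data")
    return [
        GroupData(
            label=str(lab),
            values=df.loc[df[group_col] == lab, value_col].to_numpy(dtype=float),
            is_control=(lab == control),
        )
        for lab in labels
    ]
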