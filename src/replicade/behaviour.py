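"""Forced-swim-test immobility ANOVA.

Immobility time over the 5-minute scored exposure is the depression-like
readout: the depression-sensitive line floats more. Each cohort is tested
with a one-way line ANOVA; the combined analysis adds cohort as a second
additive factor (no interaction, so 38 animals leave 35 residual df). A
helper reconstructs the one-way F from published group means, SEMs and
group sizes, which is exact because the one-way F is a function of those
summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ValidationError


@dataclass
class GroupSummary:
    """Mean, SEM and size of one line group (seconds)."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValidationError("GroupSummary.sem must be >= 0")
        if self.n < 2:
            raise ValidationError("GroupSummary.n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class AnovaResult:
    factor: str
    F: float
    df_num: int
    df_den: int
    p: float


def summarise(records: pd.DataFrame) -> dict[str, GroupSummary]:
    """Per-line GroupSummary of one cohort's immobility records."""
    out = {}
    for line, grp in records.groupby("line"):
        x = grp["immobility_s"].to_numpy(float)
        out[line] = GroupSummary(mean=float(x.mean()),
                                 sem=float(x.std(ddof=1) / np.sqrt(len(x))),
                                 n=len(x))
    return out


def anova_oneway(records: pd.DataFrame) -> AnovaResult:
    """One-way line ANOVA for a single cohort: F with (1, n_total - 2) df."""
    groups = [g["immobility_s"].to_numpy(float)
              for _, g in records.groupby("line")]
    if len(groups) != 2:
        raise ValidationError("expected exactly two line groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each line group needs n >= 2")
    F, p = stats.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    return AnovaResult("line", float(F), 1, n_total - 2, float(p))


def anova_from_summary(a: GroupSummary, b: GroupSummary) -> AnovaResult:
    """One-way F reconstructed from two groups' means, SEMs and sizes.

    SS_within = sum (n_i - 1) sd_i^2 with sd_i = sem_i * sqrt(n_i);
    SS_between = n_a n_b / (n_a + n_b) * (mean_a - mean_b)^2. Agrees
    exactly with :func:`anova_oneway` on records realising the summaries.
    """
    ss_within = (a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2
    ss_between = a.n * b.n / (a.n + b.n) * (a.mean - b.mean) ** 2
    df_den = a.n + b.n - 2
    ms_within = ss_within / df_den
    F = ss_between / ms_within if ms_within > 0 else (
        0.0 if ss_between == 0 else np.inf)
    p = float(stats.f.sf(F, 1, df_den))
    return AnovaResult("line", float(F), 1, df_den, p)


def anova_twofactor(records: pd.DataFrame) -> list[AnovaResult]:
    """Additive line + cohort ANOVA over both cohorts (type II tests).

    The model estimates three means (grand, line shift, cohort shift), so
    the residual df is n_total - 3 for both factors.
    """
    for col in ("line", "cohort", "immobility_s"):
        if col not in records.columns:
            raise ValidationError(f"swim records missing column {col!r}")
    if records["cohort"].nunique() < 2:
        raise ValidationError("combined analysis needs both cohorts")
    if records["line"].nunique() < 2:
        raise ValidationError("combined analysis needs both lines")
    fit = smf.ols("immobility_s ~ C(line) + C(cohort)", data=records).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = []
    for factor, label in (("C(line)", "line"), ("C(cohort)", "cohort")):
        row = table.loc[factor]
        out.append(AnovaResult(label, float(row["F"]), int(row["df"]),
                               int(fit.df_resid), float(row["PR(>F)"])))
    return out
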