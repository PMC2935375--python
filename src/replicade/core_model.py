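"""Per-probeset fixed-effects ANOVA with rat-line contrasts.

Each probeset (or qPCR assay) is modelled on the log2 scale as

    y = mu + line + cohort + line:cohort + batch(cohort) [+ covariates] + e

with full-rank treatment coding. Rat line is compared FSL minus FRL three
ways: within cohort 1, within cohort 2, and combined (the unweighted mean
of the two within-cohort differences, i.e. a least-squares means contrast).
All three share the pooled residual variance of the single full-data fit,
so the per-cohort tests borrow degrees of freedom across cohorts.

Batch is a fixed factor nested in cohort: with only two labelling batches
per cohort a random-effect variance component would be estimated from one
degree of freedom, so the fixed-effects formulation is used; in balanced
designs the line contrast coincides with the mixed-model estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfoundingError, ValidationError

LINES = ("FRL", "FSL")
REGIONS = ("HIP", "P/FC")

#: Columns a sample sheet must carry.
SHEET_COLUMNS = ("sample", "animal", "line", "cohort", "batch", "region")


def validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet's invariants and return it with clean dtypes.

    Raises
    ------
    SchemaError
        If required columns are missing.
    ValidationError
        On duplicate sample ids, unknown line levels, or a batch label
        spanning two cohorts (batches are nested in cohort).
    """
    from .errors import SchemaError

    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["cohort"] = sheet["cohort"].astype(int)
    dup = sheet["sample"][sheet["sample"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    bad = set(sheet["line"]) - set(LINES)
    if bad:
        raise ValidationError(f"unknown line levels: {sorted(bad)}")
    span = sheet.groupby("batch")["cohort"].nunique()
    crossing = span[span > 1]
    if len(crossing):
        raise ValidationError(
            f"batch labels spanning multiple cohorts: {sorted(crossing.index)}"
        )
    return sheet


@dataclass
class DesignMatrix:
    """Full-rank treatment-coded design aligned with a sample sheet.

    Attributes
    ----------
    X : (n_samples, n_terms) float array
    columns : term names, e.g. ``line[FSL]``, ``batch[c1_b2]``
    term_index : name -> column position
    """

    X: np.ndarray
    columns: list[str]
    term_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.term_index = {name: j for j, name in enumerate(self.columns)}

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]


def build_design(sheet: pd.DataFrame, interaction: bool = True) -> DesignMatrix:
    """Build the treatment-coded design for line, cohort and nested batch.

    Columns: intercept; ``line[FSL]``; one indicator per non-reference
    cohort; one indicator per non-reference batch within each cohort; and,
    if ``interaction``, ``line[FSL]:cohort[c]`` terms so the line effect
    may differ between cohorts (required for per-cohort contrasts).

    Raises :class:`ConfoundingError` when the factors are aliased, e.g. a
    batch containing samples of only one line in a single-batch cohort.
    """
    sheet = validate_sheet(sheet)
    n = len(sheet)
    cohorts = sorted(sheet["cohort"].unique())
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    is_fsl = (sheet["line"] == "FSL").to_numpy(float)
    cols.append(is_fsl)
    names.append("line[FSL]")

    for c in cohorts[1:]:
        cols.append((sheet["cohort"] == c).to_numpy(float))
        names.append(f"cohort[{c}]")

    for c in cohorts:
        in_c = sheet["cohort"] == c
        batches = sorted(sheet.loc[in_c, "batch"].unique())
        for b in batches[1:]:
            cols.append(((sheet["batch"] == b) & in_c).to_numpy(float))
            names.append(f"batch[{b}]")

    if interaction:
        for c in cohorts[1:]:
            cols.append(is_fsl * (sheet["cohort"] == c).to_numpy(float))
            names.append(f"line[FSL]:cohort[{c}]")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfoundingError(
            "design matrix is rank deficient: a factor level is aliased "
            "(e.g. a batch confounded with rat line)"
        )
    return DesignMatrix(X=X, columns=names)


@dataclass
class FitResult:
    """OLS fit of one response vector on a :class:`DesignMatrix`."""

    coef: np.ndarray          # log2-scale coefficients
    sigma2: float             # unbiased residual variance, RSS / df_resid
    df_resid: int
    xtx_inv: np.ndarray       # (X'X)^-1, the coefficient covariance factor
    columns: list[str]


def fit_gene_model(y: np.ndarray, design: DesignMatrix,
                   probeset: str | None = None) -> FitResult:
    """Least-squares fit of a single log2 response on the design.

    Raises :class:`ValidationError` for non-finite responses (the message
    names the probeset when given) or when no residual degree of freedom
    remains.
    """
    y = np.asarray(y, float)
    if y.shape[0] != design.n_samples:
        raise ValidationError(
            f"response length {y.shape[0]} != design rows {design.n_samples}")
    if not np.all(np.isfinite(y)):
        who = f" in probeset {probeset!r}" if probeset else ""
        raise ValidationError(f"non-finite intensity values{who}")
    df_resid = design.n_samples - design.rank
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    X = design.X
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ y)
    rss = float(np.sum((y - X @ coef) ** 2))
    # an exact fit leaves only rounding error; snap it to zero so the
    # zero-variance contract (p = 0 with a warning flag) can trigger
    if rss < 1e-20 * max(1.0, float(np.sum(y ** 2))):
        rss = 0.0
    return FitResult(coef=coef, sigma2=rss / df_resid, df_resid=df_resid,
                     xtx_inv=xtx_inv, columns=design.columns)


@dataclass
class ContrastSpec:
    """A named weight vector over model coefficients."""

    name: str
    weights: np.ndarray


def line_contrasts(design: DesignMatrix,
                   cohorts: tuple[int, int] = (1, 2)) -> dict[str, ContrastSpec]:
    """The three FSL-vs-FRL contrasts over a two-cohort interaction design.

    With treatment coding the FSL-FRL difference is ``line[FSL]`` in the
    reference cohort and ``line[FSL] + line[FSL]:cohort[c]`` in cohort
    ``c``; the combined contrast averages the two with equal weight.
    """
    p = design.rank
    idx = design.term_index
    if "line[FSL]" not in idx:
        raise ValidationError("design has no line term")
    c1, c2 = cohorts
    inter = f"line[FSL]:cohort[{c2}]"

    w_c1 = np.zeros(p)
    w_c1[idx["line[FSL]"]] = 1.0
    w_c2 = w_c1.copy()
    if inter in idx:                  # absent for single-cohort designs
        w_c2[idx[inter]] = 1.0
    w_comb = 0.5 * (w_c1 + w_c2)
    return {
        "combined": ContrastSpec("combined", w_comb),
        "cohort1": ContrastSpec("cohort1", w_c1),
        "cohort2": ContrastSpec("cohort2", w_c2),
    }


@dataclass
class ContrastResult:
    """Estimate, test and signed fold change for one contrast."""

    name: str
    estimate: float           # log2 FSL - FRL difference
    se: float
    t: float
    p: float                  # two-sided, in (0, 1]
    fold_change: float        # signed ratio, |fc| >= 1
    zero_variance: bool = False


def test_contrast(fit: FitResult, spec: ContrastSpec) -> ContrastResult:
    """t-test of a contrast against zero using the pooled residual variance.

    A zero residual variance with a nonzero estimate yields p = 0 with the
    ``zero_variance`` flag set (and a RuntimeWarning).
    """
    w = np.asarray(spec.weights, float)
    if w.shape[0] != fit.coef.shape[0]:
        raise ValidationError("contrast weights not conformable with fit")
    est = float(w @ fit.coef)
    var = float(fit.sigma2 * (w @ fit.xtx_inv @ w))
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        if est == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn(f"zero residual variance for contrast {spec.name}",
                          RuntimeWarning, stacklevel=2)
            return ContrastResult(spec.name, est, 0.0, np.inf, 0.0,
                                  signed_fold_change(est), zero_variance=True)
    else:
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
        p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return ContrastResult(spec.name, est, se, float(t), float(p),
                          signed_fold_change(est))


def signed_fold_change(log2_diff: float) -> float:
    """Convert a log2 difference into the signed fold-change convention.

    +r means r-fold higher in FSL, -r means r-fold lower in FSL; the
    magnitude is always >= 1 (a halving is reported as -2, not 0.5).
    """
    if not np.isfinite(log2_diff):
        raise ValidationError("fold change requires a finite log2 difference")
    if log2_diff >= 0:
        return float(2.0 ** log2_diff)
    return float(-(2.0 ** (-log2_diff)))
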