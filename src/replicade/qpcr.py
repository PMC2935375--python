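"""qPCR absolute quantification, loading correction and per-assay ANOVA.

Quantification is absolute: each assay carries a standard curve fitted to
a genomic-DNA dilution series, Ct = intercept + slope * log10(copies), so
a sample's mean Ct converts directly to copies per reaction (reported per
10 ng of total RNA input). Because pipetting and RNA-quality differences
shift every assay of a sample together, a set of invariant (housekeeper)
genes is used to estimate a per-sample loading score — the first principal
component of the samples x invariant-assays matrix of log copies — which
then enters each assay's ANOVA as a continuous covariate rather than as a
divisor, so its influence is estimated per assay instead of assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import core_model
from .core_model import build_design, fit_gene_model, line_contrasts, test_contrast
from .errors import CalibrationError, ValidationError

log = logging.getLogger(__name__)

#: Copies floor applied before taking logs of non-detects.
COPY_FLOOR = 0.5
#: An RT-minus control within this many cycles of the test Ct flags the sample.
RT_MINUS_MARGIN = 5.0


@dataclass
class StandardCurve:
    """Linear calibration Ct = intercept + slope * log10(copies)."""

    slope: float        # cycles per log10(copies); negative for valid curves
    intercept: float    # cycles at 1 copy
    r2: float
    ct_min: float       # calibration range of the dilution series
    ct_max: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect per-cycle doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: pd.DataFrame) -> StandardCurve:
    """Least-squares calibration line from a dilution series.

    ``points`` needs columns ``copies`` (> 0) and ``ct``; at least three
    distinct dilution levels are required and the fitted slope must be
    negative (more template, earlier crossing).
    """
    if not {"copies", "ct"} <= set(points.columns):
        raise CalibrationError("dilution series needs 'copies' and 'ct' columns")
    copies = points["copies"].to_numpy(float)
    ct = points["ct"].to_numpy(float)
    if (copies <= 0).any():
        raise CalibrationError("dilution copies must be positive")
    if len(np.unique(copies)) < 3:
        raise CalibrationError("need >= 3 distinct dilution levels")
    res = stats.linregress(np.log10(copies), ct)
    if res.slope >= 0:
        raise CalibrationError(f"non-negative curve slope {res.slope:.3f}")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2),
                         ct_min=float(ct.min()), ct_max=float(ct.max()))


def ct_to_copies(ct: float | np.ndarray, curve: StandardCurve,
                 warn_extrapolation: bool = True):
    """Invert the standard curve: copies = 10 ** ((ct - intercept) / slope)."""
    ct = np.asarray(ct, float)
    if warn_extrapolation and np.any((ct < curve.ct_min - 1e-9) |
                                     (ct > curve.ct_max + 1e-9)):
        log.warning("Ct outside calibration range [%.2f, %.2f]; extrapolating",
                    curve.ct_min, curve.ct_max)
    out = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def measurements_to_copies(measurements: pd.DataFrame,
                           curves: dict[str, StandardCurve]) -> pd.DataFrame:
    """Average replicate Cts per assay x sample and convert to copies.

    Returns an assay x sample table of copies per 10 ng reaction input,
    floored at :data:`COPY_FLOOR`. Samples whose RT-minus control crosses
    within :data:`RT_MINUS_MARGIN` cycles of the mean test Ct are logged
    as possible genomic-DNA contamination.
    """
    need = {"assay", "sample", "ct"}
    if not need <= set(measurements.columns):
        raise ValidationError(f"qPCR measurements need columns {sorted(need)}")
    mean_ct = measurements.groupby(["assay", "sample"])["ct"].mean()
    if "rt_minus_ct" in measurements.columns:
        rt = measurements.groupby(["assay", "sample"])["rt_minus_ct"].mean()
        flagged = mean_ct.index[(rt - mean_ct) < RT_MINUS_MARGIN]
        for assay, sample in flagged:
            log.warning("RT-minus within %.0f cycles of test Ct: %s / %s",
                        RT_MINUS_MARGIN, assay, sample)
    rows = {}
    for assay, per_sample in mean_ct.groupby(level="assay"):
        if assay not in curves:
            raise ValidationError(f"no standard curve for assay {assay!r}")
        copies = ct_to_copies(per_sample.to_numpy(), curves[assay])
        rows[assay] = pd.Series(np.maximum(copies, COPY_FLOOR),
                                index=per_sample.index.get_level_values("sample"))
    return pd.DataFrame(rows).T


def select_invariant(de: pd.DataFrame, matrix, expression_quantile: float = 0.5,
                     cv_bound: float = 0.3, p_floor: float = 0.5) -> list[str]:
    """Pick well-expressed, invariant genes to serve as loading controls.

    A gene qualifies when its mean intensity exceeds the given quantile of
    all gene means, its coefficient of variation is below ``cv_bound``,
    and all three line-contrast p-values exceed ``p_floor`` (no hint of a
    line effect). The list is returned ranked by CV, most stable first.
    """
    values = matrix.values if hasattr(matrix, "values") else matrix
    means = values.mean(axis=1)
    cv = values.std(axis=1, ddof=1) / means
    well_expressed = means > means.quantile(expression_quantile)
    stable = cv < cv_bound
    de = de.set_index("probeset")
    pcols = [c for c in ("p_combined", "p_cohort1", "p_cohort2") if c in de.columns]
    flat = (de[pcols] > p_floor).all(axis=1).reindex(values.index, fill_value=False)
    ok = well_expressed & stable & flat
    selected = cv[ok].sort_values().index.to_list()
    if not selected:
        log.warning("no invariant genes passed the selection criteria")
    return selected


def compute_loading_scores(copy_table: pd.DataFrame) -> pd.Series:
    """Per-sample RNA-loading score from invariant-assay log copies.

    ``copy_table`` is assays x samples restricted to invariant assays.
    The score is the first principal component of the samples x assays
    matrix of log2 copies after column centring, with its sign fixed so
    that a higher score means more RNA loaded (positive correlation with
    mean log copies). Scores are centred at zero by construction.
    """
    if copy_table.shape[0] < 2:
        raise ValidationError("need >= 2 invariant assays for a loading score")
    if copy_table.shape[1] < 3:
        raise ValidationError("need >= 3 samples for a loading score")
    X = np.log2(copy_table.to_numpy(float)).T     # samples x assays
    if not np.all(np.isfinite(X)):
        raise ValidationError("degenerate invariant-assay matrix (non-finite log copies)")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        # all samples identical: no loading variation, every score is 0
        return pd.Series(0.0, index=copy_table.columns, name="loading_score")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    score = U[:, 0] * s[0]
    mean_log = X.mean(axis=1)
    if np.corrcoef(score, mean_log)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=copy_table.columns, name="loading_score")


def qpcr_de(copy_table: pd.DataFrame, sheet: pd.DataFrame,
            scores: pd.Series | None = None, alpha: float = 0.05,
            max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Per-assay line/cohort ANOVA on log2 copies with loading covariate.

    Fits the same linear model as the expression pipeline to each assay's
    log2 copy numbers, adding the loading score as a continuous covariate
    when given, and reports signed fold changes and p-values for the
    combined and per-cohort FSL-vs-FRL contrasts. Assays missing more
    than ``max_missing_frac`` of samples are dropped with a warning.
    """
    sheet = core_model.validate_sheet(sheet)
    samples = [s for s in sheet["sample"] if s in copy_table.columns]
    if not samples:
        raise ValidationError("no overlap between sheet and copy table samples")
    sheet = sheet.set_index("sample").loc[samples].rename_axis("sample").reset_index()
    design = build_design(sheet, interaction=True)
    if scores is not None:
        scores = scores.reindex(samples)
        if scores.isna().any():
            raise ValidationError("loading scores missing for some samples")
        X = np.column_stack([design.X, scores.to_numpy(float)])
        design = core_model.DesignMatrix(X=X, columns=design.columns + ["loading"])
    specs = line_contrasts(design)

    rows = []
    for assay, copies in copy_table.iterrows():
        y = copies.reindex(samples)
        n_missing = int(y.isna().sum())
        if n_missing > max_missing_frac * len(samples):
            log.warning("assay %s dropped: %d/%d samples missing",
                        assay, n_missing, len(samples))
            continue
        if (y.dropna() <= 0).any():
            raise ValidationError(f"non-positive copies for assay {assay!r}")
        if n_missing:
            keep = ~y.isna().to_numpy()
            sub = core_model.DesignMatrix(X=design.X[keep],
                                          columns=list(design.columns))
            fit = fit_gene_model(np.log2(y.to_numpy(float)[keep]), sub, str(assay))
        else:
            fit = fit_gene_model(np.log2(y.to_numpy(float)), design, str(assay))
        row = {"assay": assay}
        for name, spec in specs.items():
            res = test_contrast(fit, spec)
            row[f"fc_{name}"] = res.fold_change
            row[f"p_{name}"] = res.p
            row[f"est_{name}"] = res.estimate
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out[["assay", "fc_combined", "p_combined", "fc_cohort1",
                   "p_cohort1", "fc_cohort2", "p_cohort2",
                   "est_combined", "est_cohort1", "est_cohort2"]]
    return out
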