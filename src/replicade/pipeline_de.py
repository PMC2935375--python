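"""Expression-matrix preprocessing and per-probeset DE orchestration.

The preprocessing follows the classic two-colour-era recipe for one-channel
arrays: median-scale every array to a common level (a transparent stand-in
for the proprietary cross-array normalisation used on the original scanner
output; it can be switched off for pre-normalised input), drop probesets
not convincingly expressed in every rat line, log2-transform, then fit the
line/cohort/batch ANOVA to every probeset and test the three FSL-vs-FRL
contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import core_model
from .core_model import DesignMatrix, build_design, line_contrasts, validate_sheet
from .errors import ValidationError

log = logging.getLogger(__name__)

CONTRASTS = ("combined", "cohort1", "cohort2")

#: DETable columns, mirroring the published per-gene result layout.
DETABLE_COLUMNS = [
    "probeset", "region",
    "fc_combined", "p_combined",
    "fc_cohort1", "p_cohort1",
    "fc_cohort2", "p_cohort2",
    "est_combined", "est_cohort1", "est_cohort2",
    "q_combined",
]


@dataclass
class ExpressionMatrix:
    """Probesets x samples intensity table in arbitrary scanner units."""

    values: pd.DataFrame  # index = probeset ids, columns = sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate probeset ids in expression matrix")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if (v.to_numpy() < 0).any():
            raise ValidationError("negative intensities in expression matrix")

    @property
    def probesets(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterRule:
    """Expression filter: intensity > threshold in >= fraction of each line."""

    threshold: float = 30.0
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("FilterRule.threshold must be >= 0")
        if not 0 < self.fraction <= 1:
            raise ValidationError("FilterRule.fraction must be in (0, 1]")


def normalize_arrays(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-scale each sample to the global median of sample medians.

    Within-sample structure is preserved exactly (each column is multiplied
    by one scalar); a sample whose median intensity is zero cannot be
    scaled and raises :class:`ValidationError`.
    """
    if m.values.shape[1] < 2:
        raise ValidationError("normalisation needs >= 2 samples")
    medians = m.values.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise ValidationError(f"samples with non-positive median intensity: {bad}")
    target = float(np.median(medians.to_numpy()))
    scaled = m.values * (target / medians)
    return ExpressionMatrix(scaled)


def filter_expressed(m: ExpressionMatrix, sheet: pd.DataFrame,
                     rule: FilterRule | None = None) -> ExpressionMatrix:
    """Keep probesets expressed above threshold in every rat line.

    A probeset is retained when its intensity is strictly greater than
    ``rule.threshold`` in at least ``rule.fraction`` of the samples of
    EACH line (lines pooled across cohorts); failing in either line drops
    it. Probeset order is preserved and the operation is idempotent.
    """
    rule = rule or FilterRule()
    sheet = validate_sheet(sheet)
    missing = set(m.samples) - set(sheet["sample"])
    if missing:
        raise ValidationError(f"samples absent from sheet: {sorted(missing)}")
    keep = pd.Series(True, index=m.probesets)
    for line in core_model.LINES:
        cols = sheet.loc[sheet["line"] == line, "sample"]
        cols = [c for c in cols if c in m.samples]
        if not cols:
            continue
        frac_above = (m.values[cols] > rule.threshold).mean(axis=1)
        keep &= frac_above >= rule.fraction
    if not keep.any():
        log.warning("expression filter removed every probeset")
    return ExpressionMatrix(m.values.loc[keep])


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> pd.DataFrame:
    """log2 of intensities floored at ``floor`` (background guard)."""
    return np.log2(m.values.clip(lower=floor))


def _fit_all(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorised OLS of every probeset row of Y on the shared design."""
    X = design.X
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv.T          # (genes, p)
    resid = Y - coef @ X.T
    sigma2 = np.sum(resid ** 2, axis=1) / df_resid
    return coef, sigma2, xtx_inv, df_resid


def run_de(m: ExpressionMatrix, sheet: pd.DataFrame, alpha: float = 0.05,
           log_floor: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Fit the ANOVA to every probeset of one region and test the contrasts.

    Expects a normalised, filtered matrix for a single region. Returns the
    DETable (rows sorted by probeset id) and a run summary with the number
    of probesets significant at ``alpha`` per contrast.
    """
    sheet = validate_sheet(sheet)
    regions = sheet.loc[sheet["sample"].isin(m.samples), "region"].unique()
    if len(regions) > 1:
        raise ValidationError(f"samples from multiple regions in one run: {sorted(regions)}")
    region = regions[0] if len(regions) else "NA"

    sheet = sheet.set_index("sample").loc[m.samples].rename_axis("sample").reset_index()
    design = build_design(sheet, interaction=True)
    specs = line_contrasts(design)

    Y = log2_transform(m, floor=log_floor).to_numpy()
    if not np.all(np.isfinite(Y)):
        bad = m.probesets[~np.isfinite(Y).all(axis=1)]
        raise ValidationError(f"non-finite intensities in probesets {list(bad[:5])}")
    coef, sigma2, xtx_inv, df_resid = _fit_all(Y, design)

    out: dict[str, np.ndarray] = {}
    for name in CONTRASTS:
        w = specs[name].weights
        est = coef @ w
        var = sigma2 * float(w @ xtx_inv @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), np.where(est == 0, 0.0, np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        p[(var == 0) & (est != 0)] = 0.0
        fc = np.where(est >= 0, 2.0 ** est, -(2.0 ** (-est)))
        out[f"est_{name}"] = est
        out[f"p_{name}"] = p
        out[f"fc_{name}"] = fc

    table = pd.DataFrame({"probeset": m.probesets, "region": region, **out})
    table["q_combined"] = multipletests(table["p_combined"], method="fdr_bh")[1]
    table = table.sort_values("probeset", kind="mergesort").reset_index(drop=True)
    table = table[DETABLE_COLUMNS]

    summary = {
        "region": region,
        "n_probesets": len(table),
        "alpha": alpha,
        **{f"n_sig_{c}": int((table[f"p_{c}"] <= alpha).sum()) for c in CONTRASTS},
    }
    log.info("run_de %s: %d probesets, sig combined/c1/c2 = %d/%d/%d",
             region, summary["n_probesets"], summary["n_sig_combined"],
             summary["n_sig_cohort1"], summary["n_sig_cohort2"])
    return table, summary
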