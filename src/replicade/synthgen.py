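"""Synthetic two-cohort, two-region expression studies with ground truth.

The generator emulates the statistical structure of a selectively-bred
rat depression-model study: two temporally distinct animal cohorts (12+9
and 10+8 animals of the control and depression-sensitive lines), both the
hippocampus and prefrontal/frontal cortex profiled from every animal,
labelling batches nested within cohort, and mostly sub-2-fold line effects
with a heavy tail reaching roughly 40-fold. Alongside the expression
matrices it produces matching qPCR measurements (standard-curve based
absolute quantification with per-sample RNA-loading factors) and
forced-swim immobility records, plus the ground truth needed for
parameter-recovery tests.

All randomness flows from a single seed through spawned child streams, so
identical (config, seed) pairs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline_de import ExpressionMatrix

REGIONS = ("HIP", "P/FC")

#: Default qPCR assay panel: name -> true FSL/FRL copy ratio. Mirrors the
#: shape of a validation panel: one extreme down-regulated gene, a strong
#: up-regulated one, a couple of subtle receptor-sized changes, and four
#: invariant loading controls (ratio exactly 1).
DEFAULT_ASSAYS: dict[str, float] = {
    "GENE_DOWN40": 1 / 40.0,
    "GENE_UP4": 4.0,
    "GENE_UP1.3": 1.3,
    "GENE_DOWN2": 0.5,
    "INV1": 1.0,
    "INV2": 1.0,
    "INV3": 1.0,
    "INV4": 1.0,
}

#: Forced-swim group means and SDs (seconds) by (cohort, line); the SDs are
#: reconstructed from reported SEMs via SD = SEM * sqrt(n).
DEFAULT_SWIM_GROUPS: dict[tuple[int, str], tuple[float, float]] = {
    (1, "FSL"): (160.3, 15.6 * np.sqrt(9)),
    (1, "FRL"): (98.1, 14.5 * np.sqrt(12)),
    (2, "FSL"): (99.8, 23.1 * np.sqrt(8)),
    (2, "FRL"): (41.0, 7.9 * np.sqrt(10)),
}


@dataclass
class StudyConfig:
    """Parameters of a synthetic two-cohort expression study.

    Expression effects, offsets and noise all live on the log2 scale;
    intensities are exponentiated and clipped at ``floor`` at the end.
    """

    n_probesets: int = 31099
    cohort_sizes: dict[int, dict[str, int]] = field(
        default_factory=lambda: {1: {"FRL": 12, "FSL": 9},
                                 2: {"FRL": 10, "FSL": 8}})
    n_batches_per_cohort: int = 2
    frac_de: float = 0.1
    # effect-size mixture: bulk below 2-fold, tail reaching ~40-fold
    bulk_sd: float = 0.35
    tail_frac: float = 0.05
    tail_max_lfc: float = float(np.log2(40))
    frac_shared_regions: float = 0.6   # P(a DE probeset affects both regions)
    cohort_sd: float = 0.1
    batch_sd: float = 0.1
    residual_sd: float = 0.25
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 2.0
    floor: float = 1.0
    # qPCR arm
    assays: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ASSAYS))
    qpcr_base_log10_copies: float = 3.0
    qpcr_ct_sd: float = 0.15           # cycles, per replicate
    loading_sd: float = 0.25           # log2 per-sample RNA loading factor
    n_replicates: int = 3
    curve_slope: float = -3.3219280948873623   # cycles per log10(copies); 100% eff
    curve_intercept: float = 40.0
    rt_minus_ct: float = 40.0          # no-amplification ceiling
    # forced-swim arm
    swim_groups: dict[tuple[int, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SWIM_GROUPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 1:
            raise ValidationError("n_probesets must be a positive integer")
        if not 0 <= self.frac_de <= 1:
            raise ValidationError("frac_de must lie in [0, 1]")
        if not 0 <= self.frac_shared_regions <= 1:
            raise ValidationError("frac_shared_regions must lie in [0, 1]")
        for name in ("bulk_sd", "cohort_sd", "batch_sd", "residual_sd",
                     "baseline_log_sd", "qpcr_ct_sd", "loading_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for c, counts in self.cohort_sizes.items():
            for line, k in counts.items():
                if k < 2:
                    raise ValidationError(
                        f"cohort_sizes[{c}][{line}] must be >= 2")
        if self.n_batches_per_cohort < 1:
            raise ValidationError("n_batches_per_cohort must be >= 1")
        for key, (_, sd) in self.swim_groups.items():
            if sd < 0:
                raise ValidationError(f"swim_groups[{key}] SD must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class StudyTruth:
    """Ground truth behind one synthetic study."""

    line_effects: pd.DataFrame     # probesets x regions, true log2 FSL-FRL
    assay_ratios: dict[str, float]  # qPCR: true FSL/FRL copy ratio
    loading_factors: pd.Series | None  # per animal, log2 RNA loading
    swim_means: dict[tuple[int, str], float]

    @property
    def n_de(self) -> int:
        return int((self.line_effects != 0).any(axis=1).sum())


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    expression: dict[str, ExpressionMatrix]  # region -> matrix
    sheets: dict[str, pd.DataFrame]          # region -> sample sheet
    qpcr: "QpcrDataset"
    swim: pd.DataFrame                       # animal, line, cohort, immobility_s
    truth: StudyTruth


@dataclass
class QpcrDataset:
    """Raw qPCR measurements plus per-assay dilution series."""

    measurements: pd.DataFrame  # assay, sample, replicate, ct, rt_minus_ct
    dilutions: pd.DataFrame     # assay, copies, ct
    sheet: pd.DataFrame         # sample sheet (one row per animal)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _make_animals(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Animal table with balanced random batch assignment within cohort.

    Batch assignment is stratified by line so that each labelling batch
    carries a near-equal share of both lines (mirrors randomised sample
    processing; also keeps line estimable when batches are in the model).
    """
    rows = []
    for cohort in sorted(config.cohort_sizes):
        batches = [f"c{cohort}_b{b + 1}" for b in range(config.n_batches_per_cohort)]
        for line in ("FRL", "FSL"):
            n = config.cohort_sizes[cohort][line]
            assignment = np.tile(batches, n // len(batches) + 1)[:n]
            assignment = rng.permutation(assignment)
            for i in range(n):
                rows.append({
                    "animal": f"c{cohort}_{line}_{i + 1:02d}",
                    "line": line, "cohort": cohort, "batch": assignment[i],
                })
    return pd.DataFrame(rows)


def _draw_line_effects(config: StudyConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """True log2 line effects per probeset and region.

    A Bernoulli(frac_de) draw selects DE probesets. Each DE probeset gets
    an effect from the bulk/tail mixture: with probability ``tail_frac`` a
    uniform draw on [1, tail_max_lfc] log2 units with random sign, else a
    zero-mean normal (sd ``bulk_sd``) truncated to |effect| < 1. The
    probeset then affects both regions (probability
    ``frac_shared_regions``, same effect in both) or a single random one.
    """
    n = config.n_probesets
    ids = [f"ps{i + 1:06d}_at" for i in range(n)]
    effects = pd.DataFrame(0.0, index=pd.Index(ids, name="probeset"),
                           columns=list(REGIONS))
    is_de = rng.random(n) < config.frac_de
    for i in np.flatnonzero(is_de):
        if rng.random() < config.tail_frac:
            mag = rng.uniform(1.0, config.tail_max_lfc)
            eff = mag * (1 if rng.random() < 0.5 else -1)
        else:
            eff = rng.normal(0.0, config.bulk_sd) if config.bulk_sd > 0 else 0.5
            while abs(eff) >= 1.0:
                eff = rng.normal(0.0, config.bulk_sd)
        if rng.random() < config.frac_shared_regions:
            effects.iloc[i, :] = eff
        else:
            effects.iloc[i, int(rng.random() < 0.5)] = eff
    return effects


def generate_study(config: StudyConfig) -> StudyData:
    """Generate one full synthetic study (expression, qPCR, swim, truth).

    For sample s and probeset g the reported intensity is
    ``2**(baseline_g + effect_g * [s is FSL] + cohort_offset + batch_offset
    + noise)`` clipped below at ``config.floor``. Cohort and batch offsets
    are gene-specific technical shifts drawn per region.
    """
    r_animal, r_effect, r_hip, r_pfc, r_qpcr, r_swim = _streams(config.seed, 6)
    animals = _make_animals(config, r_animal)
    effects = _draw_line_effects(config, r_effect)

    expression: dict[str, ExpressionMatrix] = {}
    sheets: dict[str, pd.DataFrame] = {}
    for region, rng in zip(REGIONS, (r_hip, r_pfc)):
        sheet = animals.copy()
        sheet["region"] = region
        tag = region.replace("/", "")
        sheet["sample"] = sheet["animal"] + "_" + tag
        sheet = sheet[["sample", "animal", "line", "cohort", "batch", "region"]]

        n_g, n_s = config.n_probesets, len(sheet)
        baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_g)
        log2_y = np.tile(baseline[:, None], (1, n_s))
        is_fsl = (sheet["line"] == "FSL").to_numpy()
        log2_y += np.outer(effects[region].to_numpy(), is_fsl)
        for cohort in sorted(config.cohort_sizes):
            off = rng.normal(0.0, config.cohort_sd, n_g)
            log2_y += np.outer(off, (sheet["cohort"] == cohort).to_numpy())
        for batch in sorted(sheet["batch"].unique()):
            off = rng.normal(0.0, config.batch_sd, n_g)
            log2_y += np.outer(off, (sheet["batch"] == batch).to_numpy())
        log2_y += rng.normal(0.0, config.residual_sd, (n_g, n_s))
        values = pd.DataFrame(np.maximum(2.0 ** log2_y, config.floor),
                              index=effects.index.copy(),
                              columns=sheet["sample"].to_list())
        expression[region] = ExpressionMatrix(values)
        sheets[region] = sheet

    truth = StudyTruth(line_effects=effects,
                       assay_ratios=dict(config.assays),
                       loading_factors=None,
                       swim_means={k: m for k, (m, _) in config.swim_groups.items()})
    qpcr = generate_qpcr(truth, config, animals=animals, rng=r_qpcr)
    swim = generate_swim(config, animals=animals, rng=r_swim)
    return StudyData(expression=expression, sheets=sheets, qpcr=qpcr,
                     swim=swim, truth=truth)


def generate_qpcr(truth: StudyTruth, config: StudyConfig,
                  animals: pd.DataFrame | None = None,
                  rng: np.random.Generator | None = None) -> QpcrDataset:
    """Generate qPCR measurements consistent with the study truth.

    Each animal receives a log2 loading factor ~ N(0, loading_sd) common
    to all assays (RNA input variation). True copies per reaction are
    ``base_assay * ratio**[FSL] * 2**loading``; replicate Cts follow the
    configured standard curve plus N(0, ct_sd) cycles. Reverse-
    transcriptase-minus controls sit at the no-amplification ceiling.
    A five-point 10-fold dilution series is emitted per assay (noise-free;
    calibration error is not the phenomenon under study).
    """
    if not truth.assay_ratios:
        raise ValidationError("assay list is empty")
    if rng is None:
        rng = _streams(config.seed, 6)[4]
    if animals is None:
        animals = _make_animals(config, _streams(config.seed, 6)[0])

    loading = pd.Series(rng.normal(0.0, config.loading_sd, len(animals)),
                        index=animals["animal"].to_list(), name="log2_loading")
    truth.loading_factors = loading

    dil_rows = []
    meas_rows = []
    for assay, ratio in truth.assay_ratios.items():
        base = 10.0 ** config.qpcr_base_log10_copies
        for copies in (1e2, 1e3, 1e4, 1e5, 1e6):
            dil_rows.append({"assay": assay, "copies": copies,
                             "ct": config.curve_intercept
                                   + config.curve_slope * np.log10(copies)})
        for _, a in animals.iterrows():
            copies = base * (ratio if a["line"] == "FSL" else 1.0)
            copies *= 2.0 ** loading[a["animal"]]
            true_ct = config.curve_intercept + config.curve_slope * np.log10(copies)
            for rep in range(1, config.n_replicates + 1):
                meas_rows.append({
                    "assay": assay, "sample": a["animal"], "replicate": rep,
                    "ct": true_ct + rng.normal(0.0, config.qpcr_ct_sd),
                    "rt_minus_ct": config.rt_minus_ct,
                })
    sheet = animals.copy()
    sheet["sample"] = sheet["animal"]
    sheet["region"] = "HIP"  # qPCR arm analysed per tissue; one tissue emulated
    sheet = sheet[["sample", "animal", "line", "cohort", "batch", "region"]]
    return QpcrDataset(measurements=pd.DataFrame(meas_rows),
                       dilutions=pd.DataFrame(dil_rows), sheet=sheet)


def generate_swim(config: StudyConfig, animals: pd.DataFrame | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Forced-swim immobility records, truncated to the 0-300 s window."""
    if rng is None:
        rng = _streams(config.seed, 6)[5]
    if animals is None:
        animals = _make_animals(config, _streams(config.seed, 6)[0])
    keys = list(zip(animals["cohort"].astype(int), animals["line"]))
    missing = sorted({k for k in keys if k not in config.swim_groups})
    if missing:
        raise ValidationError(f"no swim group configured for {missing}")
    means = np.array([config.swim_groups[k][0] for k in keys])
    sds = np.array([config.swim_groups[k][1] for k in keys])
    times = rng.normal(means, sds)  # scale 0 reproduces the mean exactly
    return pd.DataFrame({
        "animal": animals["animal"].to_numpy(),
        "line": animals["line"].to_numpy(),
        "cohort": animals["cohort"].astype(int).to_numpy(),
        "immobility_s": np.clip(times, 0.0, 300.0),
    })


def null_config(**overrides) -> StudyConfig:
    """A convenience config with no true line effects anywhere."""
    base = StudyConfig(frac_de=0.0,
                       assays={k: 1.0 for k in DEFAULT_ASSAYS})
    return replace(base, **overrides)
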