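"""End-to-end orchestration of a two-cohort study analysis.

Stage order mirrors the study itself: forced-swim behaviour first (the
model's phenotype check), then per-region differential expression, the
dual-cohort replication filter with cross-region overlap, and finally the
qPCR validation arm. Stage counts are logged and collected into one JSON
study report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import behaviour, io, qpcr, replication
from .errors import ReplicadeError
from .pipeline_de import ExpressionMatrix, FilterRule, filter_expressed, \
    normalize_arrays, run_de
from .synthgen import QpcrDataset, StudyData

log = logging.getLogger(__name__)

#: Probesets on the full expression array; used when chance expectations
#: should refer to the whole array rather than the filtered universe.
FULL_ARRAY_N = 31099


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run."""

    alpha: float = 0.05
    filter_threshold: float = 30.0
    filter_fraction: float = 0.5
    normalize: bool = True
    # chance-expectation universe: "filtered" or "full_array"
    expectation_n: str = "filtered"
    out_dir: Path | None = None
    qpcr_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ReplicadeError("alpha must lie in (0, 1]")
        if self.expectation_n not in ("filtered", "full_array"):
            raise ReplicadeError("expectation_n must be 'filtered' or 'full_array'")


def analyse_region(matrix: ExpressionMatrix, sheet: pd.DataFrame,
                   config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Normalise, filter and run the DE model for one region."""
    n_in = len(matrix.probesets)
    if config.normalize:
        matrix = normalize_arrays(matrix)
    rule = FilterRule(config.filter_threshold, config.filter_fraction)
    matrix = filter_expressed(matrix, sheet, rule)
    log.info("filter: %d -> %d probesets", n_in, len(matrix.probesets))
    de, summary = run_de(matrix, sheet, alpha=config.alpha)
    summary["n_input_probesets"] = n_in
    summary["n_filtered_probesets"] = len(matrix.probesets)
    return de, summary


def analyse_qpcr(dataset: QpcrDataset, config: PipelineConfig) -> dict:
    """Standard curves, copies, loading scores and per-assay ANOVA."""
    curves = {assay: qpcr.fit_standard_curve(grp)
              for assay, grp in dataset.dilutions.groupby("assay")}
    copies = qpcr.measurements_to_copies(dataset.measurements, curves)
    opts = config.qpcr_options
    invariant = opts.get("invariant_assays")
    if invariant is None:
        invariant = [a for a in copies.index if str(a).upper().startswith("INV")]
    scores = None
    if len(invariant) >= 2:
        scores = qpcr.compute_loading_scores(copies.loc[invariant])
    else:
        log.warning("fewer than 2 invariant assays; skipping loading correction")
    table = qpcr.qpcr_de(copies, dataset.sheet, scores, alpha=config.alpha)
    return {
        "curves": {a: {"slope": c.slope, "intercept": c.intercept,
                       "r2": c.r2, "efficiency": c.efficiency}
                   for a, c in curves.items()},
        "copies": copies,
        "loading_scores": scores,
        "invariant_assays": list(invariant),
        "table": table,
    }


def run_all(study: StudyData, config: PipelineConfig | None = None) -> dict:
    """Run behaviour, per-region DE, replication and qPCR on one study.

    Returns a study report dict; when ``config.out_dir`` is set the
    per-stage tables and the JSON report are also written there.
    """
    config = config or PipelineConfig()
    report: dict = {"alpha": config.alpha}

    stage = "behaviour"
    try:
        swim_results = {}
        for cohort, grp in study.swim.groupby("cohort"):
            r = behaviour.anova_oneway(grp)
            swim_results[f"cohort{cohort}"] = vars(r)
        for r in behaviour.anova_twofactor(study.swim):
            swim_results[f"combined_{r.factor}"] = vars(r)
        report["behaviour"] = swim_results

        stage = "differential expression"
        detables: dict[str, pd.DataFrame] = {}
        for region, matrix in study.expression.items():
            de, summary = analyse_region(matrix, study.sheets[region], config)
            detables[region] = de
            report.setdefault("de", {})[region] = summary

        stage = "replication"
        n_exp = FULL_ARRAY_N if config.expectation_n == "full_array" else None
        reports = {region: replication.replicated_set(de, config.alpha,
                                                      n_for_expectation=n_exp)
                   for region, de in detables.items()}
        report["replication"] = {r: rep.to_dict() for r, rep in reports.items()}
        if set(detables) == {"HIP", "P/FC"}:
            # expression filtering runs per region, so the regions' probeset
            # universes can differ; the cross-region comparison is made on
            # their intersection
            common = detables["HIP"]["probeset"][
                detables["HIP"]["probeset"].isin(detables["P/FC"]["probeset"])]
            sub = {r: de[de["probeset"].isin(common)].reset_index(drop=True)
                   for r, de in detables.items()}
            sub_reports = {r: replication.replicated_set(
                de, config.alpha, n_for_expectation=n_exp)
                for r, de in sub.items()}
            cross = replication.cross_region_overlap(
                sub_reports["HIP"], sub["HIP"],
                sub_reports["P/FC"], sub["P/FC"],
                n_for_expectation=n_exp)
            report["cross_region"] = cross.to_dict()
            report["cross_region"]["n_common_universe"] = int(len(common))

        stage = "qPCR"
        qres = analyse_qpcr(study.qpcr, config)
        report["qpcr"] = {
            "curves": qres["curves"],
            "invariant_assays": qres["invariant_assays"],
            "table": qres["table"].to_dict(orient="records"),
        }
    except ReplicadeError as err:
        raise ReplicadeError(f"stage {stage!r} failed: {err}") from err

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for region, de in detables.items():
            io.write_detable(de, out / f"de_{region.replace('/', '')}.tsv")
        qres["table"].to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
        io.write_json(report, out / "study_report.json")
    return report
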