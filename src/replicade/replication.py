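"""Dual-cohort replication filtering and chance-overlap accounting.

Instead of a multiple-testing correction, the analysis declares a probeset
differentially expressed only when it reaches p <= alpha independently in
each of two temporally distinct animal cohorts. Under the global null the
expected number of probesets passing k independent alpha-level criteria is
N * alpha**k, which turns the raw per-cohort hit lists (thousands of
probesets, mostly chance at alpha = 0.05) into a replicated set far
exceeding its chance expectation. Directional concordance — the fraction
of replicated probesets whose cohort-specific fold changes share a sign —
is the companion sanity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import SchemaError, ValidationError

_REQUIRED = ["probeset", "p_cohort1", "p_cohort2", "fc_cohort1", "fc_cohort2"]


def expected_chance_count(N: int, alpha: float, k: int = 1) -> float:
    """Expected probesets passing k independent alpha-level criteria: N*alpha**k."""
    if N < 0 or k < 1 or not 0 <= alpha <= 1:
        raise ValidationError("need N >= 0, 0 <= alpha <= 1, k >= 1")
    return N * alpha ** k


def present_count(x: float) -> int:
    """Round an expected count half-up to an integer for presentation."""
    return int(math.floor(x + 0.5))


@dataclass
class ReplicationReport:
    """Replicated-set summary for one brain region (one Venn circle pair)."""

    region: str
    alpha: float
    n_probesets: int
    n_sig_cohort1: int
    n_sig_cohort2: int
    n_replicated: int
    replicated_ids: pd.Index
    expected_k1: float       # chance hits for one alpha-level criterion
    expected_k2: float       # chance size of the two-cohort intersection
    concordance: float | None  # None when the intersection is empty

    def to_dict(self) -> dict:
        d = {
            "region": self.region, "alpha": self.alpha,
            "n_probesets": self.n_probesets,
            "n_sig_cohort1": self.n_sig_cohort1,
            "n_sig_cohort2": self.n_sig_cohort2,
            "n_replicated": self.n_replicated,
            "expected_k1": self.expected_k1,
            "expected_k1_rounded": present_count(self.expected_k1),
            "expected_k2": self.expected_k2,
            "expected_k2_rounded": present_count(self.expected_k2),
            "concordance": self.concordance,
        }
        return d


def _check_schema(de: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in de.columns]
    if missing:
        raise SchemaError(f"DETable missing per-cohort columns: {missing}")


def replicated_set(de: pd.DataFrame, alpha: float = 0.05,
                   n_for_expectation: int | None = None) -> ReplicationReport:
    """Intersect the per-cohort significant sets of one region's DETable.

    Ties at the threshold are inclusive (p <= alpha). Concordance is the
    fraction of replicated probesets with matching fold-change signs in
    the two cohorts; it is reported as None for an empty intersection.
    ``n_for_expectation`` overrides N in the chance formulas (e.g. the
    full-array probeset count when the table was pre-filtered).
    """
    _check_schema(de)
    region = str(de["region"].iloc[0]) if "region" in de.columns and len(de) else "NA"
    sig1 = de["p_cohort1"] <= alpha
    sig2 = de["p_cohort2"] <= alpha
    both = de[sig1 & sig2]
    if len(both):
        import numpy as np
        conc = float((np.sign(both["fc_cohort1"]) == np.sign(both["fc_cohort2"])).mean())
    else:
        conc = None
    N = n_for_expectation if n_for_expectation is not None else len(de)
    return ReplicationReport(
        region=region, alpha=alpha, n_probesets=len(de),
        n_sig_cohort1=int(sig1.sum()), n_sig_cohort2=int(sig2.sum()),
        n_replicated=len(both),
        replicated_ids=pd.Index(sorted(both["probeset"])),
        expected_k1=expected_chance_count(N, alpha, 1),
        expected_k2=expected_chance_count(N, alpha, 2),
        concordance=conc,
    )


@dataclass
class CrossRegionReport:
    """Overlap of the two regions' replicated sets (the four-way core)."""

    alpha: float
    n_replicated_hip: int
    n_replicated_pfc: int
    n_fourway: int
    fourway_ids: pd.Index
    pct_of_hip: float | None   # 100 * fourway / HIP replicated set
    expected_fourway: float    # chance expectation for the printed criteria
    concordance_regions: float | None
    n_hip_only: int
    n_pfc_only: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_replicated_hip": self.n_replicated_hip,
            "n_replicated_pfc": self.n_replicated_pfc,
            "n_fourway": self.n_fourway,
            "pct_of_hip": self.pct_of_hip,
            "expected_fourway": self.expected_fourway,
            "expected_fourway_rounded": present_count(self.expected_fourway),
            "concordance_regions": self.concordance_regions,
            "n_hip_only": self.n_hip_only,
            "n_pfc_only": self.n_pfc_only,
        }


def cross_region_overlap(hip_report: ReplicationReport, hip_de: pd.DataFrame,
                         pfc_report: ReplicationReport, pfc_de: pd.DataFrame,
                         n_for_expectation: int | None = None,
                         expectation_k: int = 3) -> CrossRegionReport:
    """Intersect the HIP and P/FC replicated sets and summarise the overlap.

    Both reports must come from the same alpha and the same probeset
    universe. Concordance across regions is computed on the four-way
    intersection from the combined-contrast fold-change signs. The chance
    expectation is N * alpha**expectation_k; the default k = 3 matches the
    convention of quoting the four-way count against the three extra
    alpha-level criteria beyond the first.
    """
    import numpy as np

    if hip_report.alpha != pfc_report.alpha:
        raise ValidationError("reports built at different alpha levels")
    _check_schema(hip_de)
    _check_schema(pfc_de)
    hip_ids = set(hip_de["probeset"])
    pfc_ids = set(pfc_de["probeset"])
    if hip_ids != pfc_ids:
        raise ValidationError(
            "mismatched probeset universes between regions "
            f"(symmetric difference of size {len(hip_ids ^ pfc_ids)})")

    fourway = hip_report.replicated_ids.intersection(pfc_report.replicated_ids)
    if len(fourway):
        h = hip_de.set_index("probeset").loc[fourway, "fc_combined"]
        p = pfc_de.set_index("probeset").loc[fourway, "fc_combined"]
        conc = float((np.sign(h) == np.sign(p)).mean())
    else:
        conc = None
    n_hip = hip_report.n_replicated
    N = n_for_expectation if n_for_expectation is not None else len(hip_de)
    return CrossRegionReport(
        alpha=hip_report.alpha,
        n_replicated_hip=n_hip,
        n_replicated_pfc=pfc_report.n_replicated,
        n_fourway=len(fourway),
        fourway_ids=pd.Index(sorted(fourway)),
        pct_of_hip=(100.0 * len(fourway) / n_hip) if n_hip else None,
        expected_fourway=expected_chance_count(N, hip_report.alpha, expectation_k),
        concordance_regions=conc,
        n_hip_only=n_hip - len(fourway),
        n_pfc_only=pfc_report.n_replicated - len(fourway),
    )
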