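"""Tests for qPCR calibration, loading correction and per-assay ANOVA."""

import numpy as np
import pandas as pd
import pytest

from replicade import (
    CalibrationError, StudyConfig, ValidationError, compute_loading_scores,
    ct_to_copies, fit_standard_curve, generate_study, measurements_to_copies,
    qpcr_de, select_invariant, run_de,
)

def dilution_series(slope=-3.3219280948873623, intercept=40.0,
                    copies=(1e2, 1e3, 1e4, 1e5, 1e6)):
    return pd.DataFrame({"copies": copies,
                         "ct": [intercept + slope * np.log10(c) for c in copies]})


class TestStandardCurve:
    def test_perfect_doubling_curve(self):
        curve = fit_standard_curve(dilution_series())
        assert curve.slope == pytest.approx(-3.3219280948873623)
        assert curve.intercept == pytest.approx(40.0)
        assert curve.efficiency == pytest.approx(1.0)
        assert curve.r2 == pytest.approx(1.0)

    def test_efficiency_from_shallower_slope(self):
        curve = fit_standard_curve(dilution_series(slope=-3.5))
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5) - 1, rel=1e-9)

    def test_duplicated_noiseless_points_give_perfect_r2(self):
        pts = pd.concat([dilution_series(), dilution_series()])
        assert fit_standard_curve(pts).r2 == pytest.approx(1.0)

    def test_efficiency_invariant_holds_for_noisy_fits(self):
        rng = np.random.default_rng(0)
        pts = dilution_series()
        pts["ct"] += rng.normal(0, 0.3, len(pts))
        curve = fit_standard_curve(pts)
        assert curve.efficiency == pytest.approx(
            10 ** (-1 / curve.slope) - 1, rel=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(CalibrationError, match="3 distinct"):
            fit_standard_curve(dilution_series(copies=(1e2, 1e3)))

    def test_positive_slope_rejected(self):
        with pytest.raises(CalibrationError, match="slope"):
            fit_standard_curve(dilution_series(slope=+3.3))


class TestCtToCopies:
    def test_ct_at_intercept_is_one_copy(self):
        curve = fit_standard_curve(dilution_series())
        assert ct_to_copies(40.0, curve, warn_extrapolation=False) \
            == pytest.approx(1.0)

    def test_inverting_the_line(self):
        curve = fit_standard_curve(dilution_series())
        ct = 40.0 - 3.3219280948873623 * 2  # 100 copies
        assert ct_to_copies(ct, curve, warn_extrapolation=False) \
            == pytest.approx(100.0)

    def test_one_slope_unit_divides_copies_by_ten(self):
        curve = fit_standard_curve(dilution_series())
        c1 = ct_to_copies(25.0, curve, warn_extrapolation=False)
        c2 = ct_to_copies(25.0 - curve.slope, curve, warn_extrapolation=False)
        assert c2 == pytest.approx(c1 / 10.0)

    def test_noiseless_roundtrip_exact(self):
        """copies -> Ct (via the curve) -> copies is the identity."""
        curve = fit_standard_curve(dilution_series())
        for c in (1.0, 37.5, 1e4, 2.4e6):
            ct = curve.intercept + curve.slope * np.log10(c)
            assert ct_to_copies(ct, curve, warn_extrapolation=False) \
                == pytest.approx(c, rel=1e-12)


class TestMeasurementsToCopies:
    def test_replicates_averaged_before_conversion(self):
        curve = {"A": fit_standard_curve(dilution_series())}
        meas = pd.DataFrame({
            "assay": ["A"] * 3, "sample": ["s1"] * 3,
            "replicate": [1, 2, 3], "ct": [29.0, 30.0, 31.0],
        })
        out = measurements_to_copies(meas, curve)
        expected = 10 ** ((30.0 - 40.0) / -3.3219280948873623)
        assert out.loc["A", "s1"] == pytest.approx(expected)

    def test_missing_curve_rejected(self):
        meas = pd.DataFrame({"assay": ["B"], "sample": ["s1"],
                             "replicate": [1], "ct": [30.0]})
        with pytest.raises(ValidationError, match="standard curve"):
            measurements_to_copies(meas, {})


class TestSelectInvariant:
    def test_flat_high_gene_selected_strong_effect_excluded(self, null_study,
                                                            small_study):
        de, _ = run_de(null_study.expression["HIP"], null_study.sheets["HIP"])
        m = null_study.expression["HIP"]
        genes = select_invariant(de, m, expression_quantile=0.5,
                                 cv_bound=0.5, p_floor=0.5)
        assert genes, "a null study must yield invariant candidates"
        values = m.values
        cv = values.std(axis=1, ddof=1) / values.mean(axis=1)
        assert (cv[genes] < 0.5).all()
        # ranked most-stable first
        assert list(cv[genes]) == sorted(cv[genes])
        # genes with a clear line effect must not qualify
        de_s, _ = run_de(small_study.expression["HIP"], small_study.sheets["HIP"])
        strong = de_s[de_s["p_combined"] < 1e-8]["probeset"]
        assert not set(strong) & set(
            select_invariant(de_s, small_study.expression["HIP"]))


class TestLoadingScores:
    def make_table(self, log2_copies: np.ndarray, samples, assays):
        return pd.DataFrame(2.0 ** log2_copies, index=assays, columns=samples)

    def test_identical_samples_score_zero(self):
        table = self.make_table(np.full((3, 5), 10.0),
                                [f"s{i}" for i in range(5)], ["a", "b", "c"])
        scores = compute_loading_scores(table)
        assert np.allclose(scores, 0.0)

    def test_scores_recover_injected_loading_exactly(self):
        """Rank-1 structure: common per-sample factors are the first PC."""
        rng = np.random.default_rng(1)
        base = np.tile(rng.normal(10, 1, (4, 1)), (1, 12))
        loading = rng.normal(0, 0.5, 12)
        table = self.make_table(base + loading, [f"s{i}" for i in range(12)],
                                ["a", "b", "c", "d"])
        scores = compute_loading_scores(table)
        assert abs(np.corrcoef(scores, loading)[0, 1]) > 0.999999
        assert np.corrcoef(scores, loading)[0, 1] > 0  # sign convention
        assert scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_noise_only_correlates_less_than_rank_one(self):
        rng = np.random.default_rng(2)
        loading = rng.normal(0, 0.5, 12)
        samples = [f"s{i}" for i in range(12)]
        rank1 = self.make_table(
            np.tile(rng.normal(10, 1, (2, 1)), (1, 12)) + loading,
            samples, ["a", "b"])
        noise = self.make_table(rng.normal(10, 0.5, (2, 12)), samples, ["a", "b"])
        r_rank1 = abs(np.corrcoef(compute_loading_scores(rank1), loading)[0, 1])
        r_noise = abs(np.corrcoef(compute_loading_scores(noise), loading)[0, 1])
        assert r_noise < r_rank1

    def test_too_few_assays_or_samples_rejected(self):
        with pytest.raises(ValidationError, match="2 invariant"):
            compute_loading_scores(pd.DataFrame(np.ones((1, 5))))
        with pytest.raises(ValidationError, match="3 samples"):
            compute_loading_scores(pd.DataFrame(np.ones((3, 2))))


@pytest.fixture(scope="module")
def clean_study():
    cfg = StudyConfig(n_probesets=10, qpcr_ct_sd=0.0, loading_sd=0.4,
                      seed=30,
                      assays={"TARGET": 3.0, "INV1": 1.0, "INV2": 1.0,
                              "INV3": 1.0})
    return generate_study(cfg)


class TestQpcrDe:
    def _copies(self, study):
        from replicade import fit_standard_curve, measurements_to_copies
        curves = {a: fit_standard_curve(g)
                  for a, g in study.qpcr.dilutions.groupby("assay")}
        return measurements_to_copies(study.qpcr.measurements, curves)

    def test_adjusted_estimate_recovers_true_ratio(self, clean_study):
        copies = self._copies(clean_study)
        scores = compute_loading_scores(copies.loc[["INV1", "INV2", "INV3"]])
        with pytest.warns(RuntimeWarning):  # noiseless fit -> zero residual
            table = qpcr_de(copies, clean_study.qpcr.sheet, scores)
        row = table.set_index("assay").loc["TARGET"]
        assert row["fc_combined"] == pytest.approx(3.0, rel=1e-6)

    def test_scale_invariance(self):
        cfg = StudyConfig(n_probesets=10, seed=31,
                          assays={"TARGET": 2.0, "INV1": 1.0, "INV2": 1.0})
        study = generate_study(cfg)
        copies = self._copies(study)
        a = qpcr_de(copies, study.qpcr.sheet)
        b = qpcr_de(copies * 1000.0, study.qpcr.sheet)
        np.testing.assert_allclose(
            a[["fc_combined", "p_combined"]].to_numpy(float),
            b[["fc_combined", "p_combined"]].to_numpy(float), rtol=1e-9)

    def test_loading_covariate_harmless_without_loading(self):
        """With no loading variation the covariate is near-orthogonal noise
        and leaves estimates essentially unadjusted."""
        cfg = StudyConfig(n_probesets=10, qpcr_ct_sd=0.1, loading_sd=0.0,
                          seed=32, assays={"TARGET": 2.0, "INV1": 1.0,
                                           "INV2": 1.0, "INV3": 1.0})
        study = generate_study(cfg)
        copies = self._copies(study)
        scores = compute_loading_scores(copies.loc[["INV1", "INV2", "INV3"]])
        with_cov = qpcr_de(copies, study.qpcr.sheet, scores)
        without = qpcr_de(copies, study.qpcr.sheet, None)
        a = with_cov.set_index("assay").loc["TARGET", "est_combined"]
        b = without.set_index("assay").loc["TARGET", "est_combined"]
        assert a == pytest.approx(b, abs=0.05)

    def test_correction_reduces_mse_of_ratio_estimate(self):
        """Over repeated studies with real loading variation, the adjusted
        estimator has smaller mean squared error than the unadjusted one."""
        true_log2 = np.log2(2.0)
        err_adj, err_raw = [], []
        for seed in range(40):
            cfg = StudyConfig(n_probesets=10, qpcr_ct_sd=0.05, loading_sd=0.5,
                              seed=100 + seed,
                              assays={"TARGET": 2.0, "INV1": 1.0, "INV2": 1.0,
                                      "INV3": 1.0, "INV4": 1.0})
            study = generate_study(cfg)
            copies = self._copies(study)
            scores = compute_loading_scores(
                copies.loc[["INV1", "INV2", "INV3", "INV4"]])
            adj = qpcr_de(copies, study.qpcr.sheet, scores)
            raw = qpcr_de(copies, study.qpcr.sheet, None)
            err_adj.append(adj.set_index("assay").loc["TARGET", "est_combined"]
                           - true_log2)
            err_raw.append(raw.set_index("assay").loc["TARGET", "est_combined"]
                           - true_log2)
        assert np.mean(np.square(err_adj)) < np.mean(np.square(err_raw))

    def test_nonpositive_copies_rejected(self, clean_study):
        copies = self._copies(clean_study)
        copies.iloc[0, 0] = 0.0
        with pytest.raises(ValidationError, match="non-positive"):
            qpcr_de(copies, clean_study.qpcr.sheet)
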