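"""Correlation machinery, mediation verdicts and composite scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cimpkit import (
    CohortConfig, DegenerateInputError, ExpressionMatrix, ValidationError,
    correlate, derive_verdict, mediation_report, module_activity_score,
    partial_correlation, purity_adjust, simulate_cohort, stemness_score,
)


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert correlate(x, x).r == pytest.approx(1.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = correlate(x, y).r
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlate(np.ones(10), np.arange(10.0))

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        res = correlate(x, y)
        assert res.n_effective == 3
        assert res.r == pytest.approx(1.0)


class TestPartialCorrelation:
    def test_matches_first_order_closed_form(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=120)
        x = 0.5 * z + rng.normal(size=120)
        y = -0.3 * z + 0.4 * x + rng.normal(size=120)
        res = partial_correlation(x, y, z)
        rxy, rxz, ryz = (np.corrcoef(x, y)[0, 1], np.corrcoef(x, z)[0, 1],
                         np.corrcoef(y, z)[0, 1])
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert res.r == pytest.approx(closed, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("xyzw"))
        df["y"] += 0.5 * df["z"] - 0.3 * df["w"] + 0.4 * df["x"]
        res = partial_correlation(df["x"], df["y"], df[["z", "w"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_independent_control_leaves_marginal_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        z = rng.normal(size=200)  # independent of both
        marginal = correlate(x, y).r
        partial = partial_correlation(x, y, z).r
        assert abs(partial - marginal) < 0.1

    def test_collinear_control_rejected(self):
        x = np.arange(20.0)
        y = np.arange(20.0) ** 2
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, y, x)

    def test_symmetry_in_x_and_y(self):
        rng = np.random.default_rng(9)
        x, y, z = rng.normal(size=(3, 50))
        assert partial_correlation(x, y, z).r == pytest.approx(
            partial_correlation(y, x, z).r, abs=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5),
           c=st.floats(0.1, 10), d=st.floats(-5, 5))
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(11)
        x, y, z = rng.normal(size=(3, 40))
        base = partial_correlation(x, y, z).r
        scaled = partial_correlation(a * x + b, c * y + d, 2.0 * z - 1.0).r
        assert scaled == pytest.approx(base, abs=1e-9)


class TestPurityAdjust:
    def test_score_equal_to_purity_residualizes_to_zero(self):
        idx = [f"s{i}" for i in range(10)]
        purity = pd.Series(np.linspace(0.3, 0.9, 10), index=idx)
        adjusted = purity_adjust(purity.copy(), purity)
        assert np.allclose(adjusted, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_purity(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(50)]
        purity = pd.Series(rng.beta(8, 2, 50), index=idx)
        score = pd.Series(3 * purity.to_numpy() + rng.normal(size=50), index=idx)
        adjusted = purity_adjust(score, purity)
        assert abs(np.dot(adjusted, purity - purity.mean())) < 1e-10

    def test_uncorrelated_purity_roughly_centers(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(100)]
        score = pd.Series(rng.normal(size=100), index=idx)
        purity = pd.Series(rng.beta(8, 2, 100), index=idx)
        adjusted = purity_adjust(score, purity)
        assert np.corrcoef(adjusted, score)[0, 1] > 0.95

    def test_constant_purity_warns_and_centers(self):
        idx = ["a", "b", "c", "d"]
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        purity = pd.Series(0.8, index=idx)
        with pytest.warns(UserWarning, match="constant"):
            adjusted = purity_adjust(score, purity)
        assert np.allclose(adjusted, score - score.mean())

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            purity_adjust(pd.Series([1.0, 2.0]), pd.Series([0.5, 0.6]))

    def test_missing_purity_propagates(self):
        idx = [f"s{i}" for i in range(5)]
        score = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        purity = pd.Series([0.5, 0.6, np.nan, 0.7, 0.8], index=idx)
        adjusted = purity_adjust(score, purity)
        assert np.isnan(adjusted["s2"])
        assert adjusted.drop("s2").notna().all()


class TestMediationReport:
    def _report(self, **cfg):
        c = simulate_cohort(CohortConfig(seed=42, n_samples=200, n_probes=20,
                                         n_signature_probes=5, **cfg))
        gt = c.ground_truth
        log2 = c.expression.to_log2()
        return mediation_report(
            gt.proliferation,
            {"DNMT1": log2.loc["DNMT1"], "DNMT3A": log2.loc["DNMT3A"]},
            gt.cimp_latent)

    def test_mediation_chain_detected(self):
        assert self._report().verdict == "mediation_consistent"

    def test_common_cause_structure_detected(self):
        rep = self._report(coef_dnmt_to_cimp=(0.0, 0.0), coef_prolif_to_cimp=0.7)
        assert rep.verdict == "common_cause_consistent"

    def test_pure_noise_gives_no_association(self):
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(100)]
        rep = mediation_report(
            pd.Series(rng.normal(size=100), index=idx),
            {"DNMT1": pd.Series(rng.normal(size=100), index=idx),
             "DNMT3A": pd.Series(rng.normal(size=100), index=idx)},
            pd.Series(rng.normal(size=100), index=idx))
        assert rep.verdict == "no_association"

    def test_verdict_rederivable_from_stored_statistics(self):
        rep = self._report()
        assert derive_verdict(rep) == rep.verdict


class TestCompositeScores:
    def test_stemness_single_marker_passthrough(self):
        df = pd.DataFrame({"s1": [3.0], "s2": [3.0]}, index=["SOX2"])
        em = ExpressionMatrix(df, scale="log2")
        score, missing = stemness_score(em)
        assert (score == 3.0).all()
        assert "POU5F1" in missing

    def test_stemness_aliases_map_to_hgnc(self):
        df = pd.DataFrame({"s1": [2.0, 4.0]}, index=["POU5F1", "MYC"])
        em = ExpressionMatrix(df, scale="log2")
        score, missing = stemness_score(em, marker_genes=("OCT4", "C-MYC"))
        assert score["s1"] == pytest.approx(3.0)
        assert missing == []

    def test_stemness_matches_subset_mean(self, small_expr):
        markers = small_expr.gene_ids[:4]
        score, _ = stemness_score(small_expr, marker_genes=markers)
        brute = np.log2(small_expr.values.loc[markers] + 1).mean(axis=0)
        assert np.allclose(score, brute)

    def test_stemness_no_marker_present_rejected(self, small_expr):
        with pytest.raises(ValidationError):
            stemness_score(small_expr, marker_genes=("NOPE",))

    def test_module_activity_matches_svd_oracle(self, small_expr):
        genes = small_expr.gene_ids[:20]
        score = module_activity_score(small_expr, genes)
        sub = np.log2(small_expr.values.loc[genes] + 1).to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = vt[0] * s[0]
        agree = min(np.abs(score.to_numpy() - oracle).max(),
                    np.abs(score.to_numpy() + oracle).max())
        assert agree < 1e-8

    def test_module_activity_rank1_case(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame([profile, 2 * profile + 1], index=["g1", "g2"],
                          columns=list("abcd"))
        em = ExpressionMatrix(df, scale="log2")
        score = module_activity_score(em, ["g1", "g2"])
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(np.abs(score), np.abs(z * np.sqrt(2)), atol=1e-10)
        assert np.corrcoef(score, profile)[0, 1] > 0  # sign-oriented upward

    def test_module_activity_disjoint_set_rejected(self, small_expr):
        with pytest.raises(ValidationError):
            module_activity_score(small_expr, ["x1", "x2"])
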