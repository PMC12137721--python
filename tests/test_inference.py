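"""Tests for the change-ratio regression and gene-level analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelenoise import inference, synthetic
from conftest import metrics_from_truth


def _rows(b, d, y, gene="g"):
    return pd.DataFrame({"gene": gene, "population_id": range(len(b)),
                         "eta": y, "b": b, "day": d})


def _law(base, xi_b, xi_d, b, d, d_max=3.0):
    b, d = np.asarray(b, float), np.asarray(d, float)
    return base * ((xi_b - 1) * b + 1) * ((xi_d - 1) * d / d_max + 1)


class TestFitChangeModel:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, 40)
        d = rng.integers(0, 4, 40)
        y = _law(0.5, 1.4, 1.2, b, d)
        fit = inference.fit_change_model(_rows(b, d, y), d_max=3.0)
        assert fit.status == "ok"
        assert fit.baseline == pytest.approx(0.5, abs=1e-8)
        assert fit.xi_b == pytest.approx(1.4, abs=1e-8)
        assert fit.xi_d == pytest.approx(1.2, abs=1e-8)

    def test_two_group_closed_form(self):
        # only b=0 and b=1 rows at d=0: the fitted ratio is the ratio of
        # group means
        rng = np.random.default_rng(1)
        y0 = rng.normal(0.5, 0.02, 10)
        y1 = rng.normal(0.8, 0.02, 10)
        rows = _rows(np.r_[np.zeros(10), np.ones(10)], np.zeros(20),
                     np.r_[y0, y1])
        fit = inference.fit_change_model(rows)
        assert fit.xi_b == pytest.approx(y1.mean() / y0.mean(), rel=1e-6)

    def test_model_evaluation_identities(self):
        fit = inference.NoiseModelFit(gene="g", response="eta", baseline=0.4,
                                      xi_b=1.5, xi_d=1.2)
        assert fit.predict(0.0, 0.0) == pytest.approx(0.4)
        assert fit.predict(1.0, 0.0) == pytest.approx(0.4 * 1.5)
        assert fit.predict(0.0, 1.0, d_max=1.0) == pytest.approx(0.4 * 1.2)

    def test_rank_deficient_design_flagged(self):
        rows = _rows(np.full(12, 0.5), np.full(12, 2), np.ones(12))
        fit = inference.fit_change_model(rows)
        assert fit.status == "degenerate"

    def test_too_few_populations_flagged(self):
        rows = _rows(np.r_[0.0, 1.0], np.r_[0, 3], np.r_[0.5, 0.6])
        assert inference.fit_change_model(rows).status == "failed"

    def test_type_one_error_calibrated(self):
        # under the null, about alpha of genes show p_b < alpha
        cfg = synthetic.SyntheticConfig(n_genes=300, seed=17)
        counts, meta, truth = synthetic.generate_counts(cfg)
        fits = inference.fit_all_genes(
            metrics_from_truth(counts, meta, truth), "eta")
        frac = (fits["p_b"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08


class TestClassifyChanges:
    def test_classification_rules(self):
        fits = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "xi_b": [1.3, 0.8, 1.5], "p_b": [0.2, 0.01, 0.001],
            "status": ["ok", "ok", "ok"]})
        out = inference.classify_changes(fits)
        assert out["class_b"].tolist() == ["none", "decrease", "increase"]

    def test_known_increase_fraction_recovered(self):
        # 30% of genes carry a strong true increase; the class counts must
        # land within the binomial interval implied by the generator truth
        n_genes = 100
        xi_b = np.where(np.arange(n_genes) < 30, 1.8, 1.0)
        cfg = synthetic.SyntheticConfig(n_genes=n_genes, true_xi_b=xi_b,
                                        seed=23)
        counts, meta, truth = synthetic.generate_counts(cfg)
        fits = inference.classify_changes(inference.fit_all_genes(
            metrics_from_truth(counts, meta, truth), "eta"))
        inc = fits.loc[fits["class_b"] == "increase", "gene"]
        true_inc = {f"gene{i:04d}" for i in range(30)}
        # essentially all true increases detected at this effect size...
        assert len(set(inc) & true_inc) >= 25
        # ...and false positives stay near the alpha level
        assert len(set(inc) - true_inc) <= 0.05 * 70 + 5


class TestOverallFit:
    def test_null_pool_near_one(self):
        cfg = synthetic.SyntheticConfig(n_genes=60, seed=31)
        counts, meta, truth = synthetic.generate_counts(cfg)
        mdf = metrics_from_truth(counts, meta, truth)
        fit = inference.overall_fit(mdf, "eta")
        lo, hi = fit.ci_b()
        assert lo <= 1.0 <= hi

    def test_shared_ratio_recovered_and_consistent_with_per_gene(self):
        cfg = synthetic.SyntheticConfig(n_genes=60, true_xi_b=1.38, seed=33)
        counts, meta, truth = synthetic.generate_counts(cfg)
        mdf = metrics_from_truth(counts, meta, truth)
        overall = inference.overall_fit(mdf, "eta")
        per_gene = inference.fit_all_genes(mdf, "eta")
        assert overall.xi_b == pytest.approx(1.38, rel=0.06)
        assert overall.xi_b == pytest.approx(per_gene["xi_b"].median(),
                                             rel=0.05)

    def test_permutation_null_covers_one(self):
        cfg = synthetic.SyntheticConfig(n_genes=40, true_xi_b=1.5, seed=35)
        counts, meta, truth = synthetic.generate_counts(cfg)
        mdf = metrics_from_truth(counts, meta, truth)
        rng = np.random.default_rng(0)
        mdf["b"] = rng.permutation(mdf["b"].to_numpy())
        fit = inference.overall_fit(mdf, "eta")
        lo, hi = fit.ci_b()
        assert lo <= 1.0 <= hi


class TestDecomposeNoise:
    def _fits(self, xi_d_eta, xi_d_mu):
        n = len(xi_d_eta)
        mk = lambda xi: pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)], "xi_d": xi,
            "status": ["ok"] * n})
        return mk(xi_d_eta), mk(xi_d_mu)

    def test_no_expression_change_means_all_extrinsic(self):
        eta_f, mu_f = self._fits([1.2, 1.3, 1.1, 1.25], [1.0, 1.0, 1.0, 1.0])
        dec = inference.decompose_noise(eta_f, mu_f)
        np.testing.assert_allclose(dec.per_gene["intrinsic"], 1.0)
        np.testing.assert_allclose(dec.per_gene["extrinsic"],
                                   dec.per_gene["total"])

    def test_constructed_slope_recovered(self):
        # genes built on a log-log slope of -0.5 plus noise; brute-force OLS
        # on the logs is the oracle
        rng = np.random.default_rng(2)
        xi_mu = np.exp(rng.normal(0, 0.4, 60))
        xi_eta = xi_mu ** -0.5 * np.exp(rng.normal(0, 0.05, 60))
        eta_f, mu_f = self._fits(xi_eta, xi_mu)
        dec = inference.decompose_noise(eta_f, mu_f)
        lx, ly = np.log(xi_mu), np.log(xi_eta)
        slope_oracle = np.polyfit(lx, ly, 1)[0]
        assert dec.slope == pytest.approx(slope_oracle, abs=1e-10)
        assert dec.slope == pytest.approx(-0.5, abs=3 * dec.slope_se + 0.02)

    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(3)
        eta_f, mu_f = self._fits(np.exp(rng.normal(0, 0.3, 20)),
                                 np.exp(rng.normal(0, 0.3, 20)))
        dec = inference.decompose_noise(eta_f, mu_f)
        np.testing.assert_allclose(
            dec.per_gene["intrinsic"] * dec.per_gene["extrinsic"],
            dec.per_gene["total"], rtol=1e-12)

    def test_too_few_genes_rejected(self):
        eta_f, mu_f = self._fits([1.1, 1.2], [1.0, 1.1])
        with pytest.raises(ValueError):
            inference.decompose_noise(eta_f, mu_f)


def _signed_rows(xi_plus, xi_minus, n=60, noise=0.03, seed=0, gene="g"):
    rng = np.random.default_rng(seed)
    bs = rng.uniform(-1, 1, n)
    d = rng.integers(0, 4, n)
    y = 0.5 * (1 + (xi_plus - 1) * np.clip(bs, 0, None)
               + (xi_minus - 1) * np.clip(-bs, 0, None))
    y = y * rng.normal(1, noise, n)
    return pd.DataFrame({"gene": gene, "eta": y, "b_signed": bs, "day": d})


class TestSignedBiasFit:
    def test_symmetric_null_not_significant(self):
        fit = inference.signed_bias_fit(_signed_rows(1.4, 1.4, seed=1))
        assert fit.status == "ok"
        assert fit.p_equal > 0.05

    def test_asymmetric_construction_detected(self):
        # power check over replicates at this sample size and noise level
        ps = [inference.signed_bias_fit(
            _signed_rows(1.5, 1.0, seed=s)).p_equal for s in range(10)]
        assert np.median(ps) < 0.01

    def test_mirrored_bias_swaps_ratios(self):
        rows = _signed_rows(1.5, 1.1, seed=4)
        fit = inference.signed_bias_fit(rows)
        mirrored = rows.assign(b_signed=-rows["b_signed"])
        mfit = inference.signed_bias_fit(mirrored)
        assert fit.xi_plus == pytest.approx(mfit.xi_minus, rel=1e-6)
        assert fit.xi_minus == pytest.approx(mfit.xi_plus, rel=1e-6)

    def test_single_sign_degenerate(self):
        rows = _signed_rows(1.2, 1.2, seed=5)
        rows["b_signed"] = rows["b_signed"].abs()
        assert inference.signed_bias_fit(rows).status == "degenerate"


class TestCallMonoallelic:
    def _metrics(self, gene_bias: dict, n_pops=6):
        rows = []
        for gene, b in gene_bias.items():
            for p in range(n_pops):
                rows.append({"gene": gene, "population_id": p, "b": b})
        return pd.DataFrame(rows)

    def _annotations(self, genes, imprinted):
        return pd.DataFrame({
            "gene": genes,
            "annotation": ["imprinted" if g in imprinted else "non-imprinted"
                           for g in genes],
            "parental": ["maternal"] * len(genes)})

    def test_extreme_bias_calls(self):
        m = self._metrics({"mono": 1.0, "bi": 0.0, "also_bi": 0.2})
        ann = self._annotations(["mono", "bi", "also_bi"], {"mono"})
        calls, _ = inference.call_monoallelic(m, ann)
        lookup = calls.set_index("gene")["call"]
        assert lookup["mono"] == "monoallelic"
        assert lookup["bi"] == "biallelic"
        assert lookup["also_bi"] == "biallelic"

    def test_fisher_p_matches_hypergeometric_sum(self):
        # brute-force two-sided Fisher p by summing hypergeometric point
        # probabilities no larger than the observed table's
        rng = np.random.default_rng(6)
        gene_bias = {}
        imprinted = set()
        for i in range(40):
            g = f"g{i}"
            if i < 12:
                imprinted.add(g)
                gene_bias[g] = 0.9 if i < 6 else 0.1
            else:
                gene_bias[g] = 0.8 if i < 15 else 0.05
        m = self._metrics(gene_bias)
        ann = self._annotations(list(gene_bias), imprinted)
        _, contingency = inference.call_monoallelic(m, ann)
        (a, b), (c, d) = contingency["table"]
        N, K, n = a + b + c + d, a + b, a + c
        probs = stats.hypergeom.pmf(np.arange(max(0, n - (N - K)),
                                              min(K, n) + 1), N, K, n)
        obs = stats.hypergeom.pmf(a, N, K, n)
        brute = probs[probs <= obs * (1 + 1e-9)].sum()
        assert contingency["fisher_p"] == pytest.approx(brute, rel=1e-9)

    def test_single_class_rejected(self):
        m = self._metrics({"a": 1.0, "b": 0.0})
        ann = self._annotations(["a", "b"], {"a", "b"})
        with pytest.raises(ValueError):
            inference.call_monoallelic(m, ann)


class TestDosageAssessment:
    def _fits(self, xi):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(xi))],
                             "xi_b": xi, "se_b": 0.01, "p_b": 0.5,
                             "status": "ok"})

    def test_exact_halving(self):
        out = inference.dosage_assessment(self._fits([0.5] * 5))
        assert out["median_xi_mu_b"] == pytest.approx(0.5)
        assert out["n_beyond_halving"] == 0

    def test_full_compensation(self):
        out = inference.dosage_assessment(self._fits([1.0] * 5))
        assert out["median_xi_mu_b"] == pytest.approx(1.0)
        assert out["n_beyond_halving"] == 5

    def test_mixed_cohort_median_matches_brute_force(self):
        rng = np.random.default_rng(7)
        xi = np.where(rng.random(50) < 0.8, rng.normal(0.95, 0.05, 50),
                      rng.normal(0.5, 0.02, 50))
        out = inference.dosage_assessment(self._fits(xi))
        assert out["median_xi_mu_b"] == pytest.approx(float(np.median(xi)))
        assert out["n_beyond_halving"] == int((xi > 0.5).sum())


class TestParentalOriginTest:
    def test_symmetric_groups_not_significant(self):
        rng = np.random.default_rng(8)
        fits = pd.DataFrame({
            "gene": [f"g{i}" for i in range(40)],
            "xi_b": rng.normal(1.2, 0.1, 40), "status": "ok"})
        ann = pd.DataFrame({
            "gene": fits["gene"],
            "parental": ["maternal"] * 25 + ["paternal"] * 15})
        out = inference.parental_origin_test(fits, ann)
        assert out["p_value"] > 0.05
        assert out["n_maternal"] == 25 and out["n_paternal"] == 15
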