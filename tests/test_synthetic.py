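"""Tests of the ground-truth data generators."""

import numpy as np
import pandas as pd
import pytest

from allelenoise import inference, metrics as M, popqc, synthetic
from conftest import metrics_from_truth


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0}, {"cells_per_population": -1},
        {"dispersion": 0.0}, {"bb_concentration": -2.0},
        {"ase_capture_rate": 1.5},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.SyntheticConfig(**kwargs)

    def test_unknown_cell_type_rejected(self):
        cfg = synthetic.BrainConfig(populations=(("martian", "P0"),))
        with pytest.raises(ValueError, match="cell type"):
            synthetic.generate_brain_like(cfg)


class TestGenerateCounts:
    def test_deterministic_given_seed(self):
        cfg = synthetic.SyntheticConfig(n_genes=10, cells_per_population=10,
                                        seed=5)
        a = synthetic.generate_counts(cfg)
        b = synthetic.generate_counts(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_counts_are_nonnegative_integers(self, small_dataset):
        counts = small_dataset["counts"]
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_null_model_has_no_bias_trend(self):
        # with xi_b = xi_d = 1, fitted ratio CIs should cover 1 for most genes
        cfg = synthetic.SyntheticConfig(n_genes=30, seed=21)
        counts, meta, truth = synthetic.generate_counts(cfg)
        mdf = metrics_from_truth(counts, meta, truth)
        fits = inference.fit_all_genes(mdf, "eta")
        lo = fits["xi_b"] - 1.96 * fits["se_b"]
        hi = fits["xi_b"] + 1.96 * fits["se_b"]
        covered = ((lo <= 1.0) & (1.0 <= hi)).mean()
        assert covered > 0.85

    def test_day_ratio_recovery_within_monte_carlo_interval(self):
        # oracle: independent re-fits over replicate simulations establish
        # the 95% recovery interval; a fresh fit must land inside it and the
        # replicate median must sit close to the configured ratio
        true_xi_d = 1.5
        estimates = []
        for rep in range(10):
            cfg = synthetic.SyntheticConfig(
                n_genes=25, true_xi_d=true_xi_d, seed=100 + rep)
            counts, meta, truth = synthetic.generate_counts(cfg)
            mdf = metrics_from_truth(counts, meta, truth)
            fits = inference.fit_all_genes(mdf, "eta")
            estimates.extend(fits["xi_d"].tolist())
        estimates = np.array(estimates)
        lo, hi = np.quantile(estimates, [0.025, 0.975])
        cfg = synthetic.SyntheticConfig(n_genes=25, true_xi_d=true_xi_d,
                                        seed=999)
        counts, meta, truth = synthetic.generate_counts(cfg)
        fresh = inference.fit_all_genes(
            metrics_from_truth(counts, meta, truth), "eta")["xi_d"].median()
        assert lo <= fresh <= hi
        assert abs(np.median(estimates) - true_xi_d) / true_xi_d < 0.1


class TestGenerateAse:
    def test_ref_alt_never_exceed_cell_count(self, small_dataset):
        ds = small_dataset
        per_cell_gene = ds["ase"].groupby(["cell_id", "gene"])[
            ["ref_count", "alt_count"]].sum().sum(axis=1)
        for (cell, gene), total in per_cell_gene.items():
            assert total <= ds["counts"].loc[gene, cell]

    def test_fully_monoallelic_gene(self):
        cfg = synthetic.SyntheticConfig(
            n_genes=3, n_donors=2, n_dishes=1, cells_per_population=20,
            true_bias=1.0, ase_capture_rate=1.0, seed=3)
        counts, meta, truth = synthetic.generate_counts(cfg)
        ase = synthetic.generate_ase(counts, meta, cfg, truth)
        # each (gene, donor) is phased to one allele: ref or alt always zero
        for (_, _), grp in ase.groupby(["gene", "cell_id"]):
            assert (grp["ref_count"] == 0).all() or (grp["alt_count"] == 0).all()
        bs, b = M.expression_bias(
            ase[ase["gene"] == "gene0000"].merge(
                meta[meta["donor"] == "donor0"][["cell_id"]], on="cell_id"))
        assert b == pytest.approx(1.0)

    def test_balanced_high_concentration_limit(self):
        cfg = synthetic.SyntheticConfig(
            n_genes=2, n_donors=1, n_dishes=1, n_days=1,
            cells_per_population=200, true_bias=0.0, ase_capture_rate=1.0,
            baseline_mean=200.0, bb_concentration=1e6, seed=4)
        counts, meta, truth = synthetic.generate_counts(cfg)
        ase = synthetic.generate_ase(counts, meta, cfg, truth)
        bs, b = M.expression_bias(ase[ase["gene"] == "gene0000"])
        assert b < 0.02

    def test_partial_bias_within_resampling_interval(self):
        # brute-force oracle: resample the per-cell beta-binomial process to
        # bracket where the estimated population bias magnitude should land
        true_b = 0.75
        cfg = synthetic.SyntheticConfig(
            n_genes=1, n_donors=1, n_dishes=1, n_days=1,
            cells_per_population=200, true_bias=true_b, ase_capture_rate=1.0,
            baseline_mean=100.0, seed=6)
        counts, meta, truth = synthetic.generate_counts(cfg)
        ase = synthetic.generate_ase(counts, meta, cfg, truth)
        _, b_hat = M.expression_bias(ase)

        rng = np.random.default_rng(99)
        f = (1 + true_b) / 2
        conc = cfg.bb_concentration
        reps = []
        for _ in range(300):
            p = rng.beta(f * conc, (1 - f) * conc, size=200)
            n = rng.poisson(100, size=200)
            r = rng.binomial(n, p)
            keep = n > 0
            reps.append(abs(np.mean((2 * r[keep] - n[keep]) / n[keep])))
        lo, hi = np.quantile(reps, [0.005, 0.995])
        assert lo <= b_hat <= hi

    def test_missing_population_rejected(self, small_dataset):
        ds = small_dataset
        bad_truth = dict(ds["truth"], population_ids=["nonexistent"])
        with pytest.raises(KeyError):
            synthetic.generate_ase(ds["counts"], ds["metadata"],
                                   ds["config"], bad_truth)


class TestBrainLike:
    def test_zero_loading_gives_near_zero_mi(self, brain_dataset):
        # genes outside any block are independent: MI at the estimator
        # bias floor, about 1/(2(n-1))
        cpm = popqc.cpm_normalize(brain_dataset["counts"])
        meta = brain_dataset["metadata"]
        cells = meta.loc[meta["population_id"] == "oligo|P0", "cell_id"]
        from allelenoise import minet
        mat = minet.mi_matrix(cpm.loc[:, cells], genes=[f"bgene{g:03d}"
                                                        for g in range(25, 40)])
        n = len(cells)
        floor = 1.0 / (2 * (n - 1))
        offdiag = mat.to_numpy()[np.triu_indices(len(mat), k=1)]
        assert np.nanmean(offdiag) < 5 * floor

    def test_configured_correlation_gives_closed_form_mi(self):
        # rho = 0.6 within a block: Gaussian MI = -ln(1-0.36)/2 ~ 0.223
        # block is a small fraction of the genes so CPM totals do not
        # absorb (and cancel) the shared latent factor
        cfg = synthetic.BrainConfig(
            n_genes=40, cells_per_population=2000, baseline_mean=2000.0,
            correlated_blocks=[[0, 1]],
            block_rho={("oligo", "P0"): [0.6]},
            populations=(("oligo", "P0"),), seed=11)
        counts, meta, _ = synthetic.generate_brain_like(cfg)
        cpm = popqc.cpm_normalize(counts)
        x = np.log2(cpm.iloc[0].to_numpy() + 1)
        y = np.log2(cpm.iloc[1].to_numpy() + 1)
        expected = -0.5 * np.log(1 - 0.36)
        # count sampling and the log(CPM+1) transform attenuate the realised
        # correlation slightly below the configured latent rho
        assert M.mutual_information(x, y) == pytest.approx(expected, rel=0.2)

    def test_truth_manifest_records_correlation_change(self, brain_dataset):
        truth = brain_dataset["truth"]
        # neuron lineage gains block-1 correlation with age in the defaults
        assert truth["block_rho"]["NII|P42"][1] > truth["block_rho"]["NI|P0"][1]

    def test_deterministic(self):
        cfg = synthetic.BrainConfig(n_genes=10, cells_per_population=20, seed=2)
        a = synthetic.generate_brain_like(cfg)
        b = synthetic.generate_brain_like(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
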