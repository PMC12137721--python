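"""Synthetic single-cell data with known ground truth.

Emulates the structure of the two study designs the package targets:

* an iPSC-like differentiation design — populations indexed by
  donor x day x dish, negative-binomial counts whose population-level
  coefficient of variation follows the multiplicative change law
  ``eta = eta0 * ((xi_b - 1) * b + 1) * ((xi_d - 1) * d/d_max + 1)``,
  beta-binomial allele-specific read allocation with a per-gene per-donor
  phase, and optional correlated gene blocks;
* a brain-like design — populations indexed by cell type x age with a
  configurable within-block expression correlation per population, for
  exercising the mutual-information analyses.

Every generated dataset ships with a *truth manifest* holding the exact
parameters used, so parameter-recovery can be scored without re-deriving
anything. All outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "BrainConfig", "generate_counts",
           "generate_ase", "generate_brain_like"]


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for the iPSC-like generator.

    Populations are all donor x day x dish combinations; days are coded
    0..n_days-1 and the change law is evaluated at d / (n_days - 1), so
    ``true_xi_d`` is always the full day-0 to final-day ratio.

    ``true_xi_b`` / ``true_xi_d`` scale the noise law; ``true_xi_mu_b`` /
    ``true_xi_mu_d`` scale the mean law (e.g. 0.5 models uncompensated
    halving of expression under monoallelic expression). Each may be a
    scalar or a length-``n_genes`` array. ``true_bias`` is the bias
    *magnitude* in [0, 1]; ``None`` draws one value per (gene, population)
    uniformly, a scalar or per-gene array fixes it.
    """

    n_genes: int = 200
    n_donors: int = 5
    n_days: int = 4
    n_dishes: int = 3
    cells_per_population: int = 60
    baseline_mean: float = 50.0       # mean counts/cell at b=0, d=0
    dispersion: float = 10.0          # NB size parameter (larger = closer to Poisson)
    eta0: float = 0.5                 # baseline population CV at b=0, d=0
    true_xi_b: float | np.ndarray = 1.0
    true_xi_d: float | np.ndarray = 1.0
    true_xi_mu_b: float | np.ndarray = 1.0
    true_xi_mu_d: float | np.ndarray = 1.0
    true_bias: float | np.ndarray | None = None
    snps_per_gene: int = 2
    ase_capture_rate: float = 0.3
    bb_concentration: float = 20.0
    correlated_blocks: list = field(default_factory=list)  # list of gene-index lists
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_donors", "n_days", "n_dishes",
                     "cells_per_population", "snps_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0 or self.bb_concentration <= 0:
            raise ValueError("dispersion and bb_concentration must be positive")
        if not 0 <= self.ase_capture_rate <= 1:
            raise ValueError("ase_capture_rate must lie in [0, 1]")

    def gene_array(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_genes,))
        return arr.copy()


def _population_grid(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for donor in range(config.n_donors):
        for day in range(config.n_days):
            for dish in range(config.n_dishes):
                rows.append({"donor": f"donor{donor}", "day": day,
                             "dish": f"dish{dish}",
                             "population_id": f"donor{donor}|{day}|dish{dish}"})
    return pd.DataFrame(rows)


def _change_law(base, xi_b, b, xi_d, dfrac):
    return base * ((xi_b - 1.0) * b + 1.0) * ((xi_d - 1.0) * dfrac + 1.0)


def generate_counts(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw the gene x cell count matrix, cell metadata and truth manifest.

    Within each population the per-cell gene mean is the law mean times a
    log-normal cell factor whose variance is chosen so that the *total*
    coefficient of variation across cells (Poisson + overdispersion +
    cell factor) equals the noise-law target. Genes in a correlated block
    share the latent log-normal factor, which makes their expression (and
    noise) co-vary the way genes under a common extrinsic influence do.
    """
    rng = np.random.default_rng(config.seed)
    pops = _population_grid(config)
    d_max = max(config.n_days - 1, 1)
    genes = [f"gene{g:04d}" for g in range(config.n_genes)]

    xi_b = config.gene_array(config.true_xi_b)
    xi_d = config.gene_array(config.true_xi_d)
    xi_mu_b = config.gene_array(config.true_xi_mu_b)
    xi_mu_d = config.gene_array(config.true_xi_mu_d)

    n_pops = len(pops)
    if config.true_bias is None:
        bias = rng.uniform(0.0, 1.0, size=(config.n_genes, n_pops))
    else:
        bias = np.asarray(config.true_bias, dtype=float)
        if bias.ndim == 0:
            bias = np.full((config.n_genes, n_pops), float(bias))
        elif bias.ndim == 1:
            bias = np.repeat(bias[:, None], n_pops, axis=1)
        if np.any((bias < 0) | (bias > 1)):
            raise ValueError("true_bias must lie in [0, 1]")

    block_of = np.full(config.n_genes, -1)
    for bi, members in enumerate(config.correlated_blocks):
        for g in members:
            block_of[g] = bi

    meta_rows, count_cols = [], []
    r = config.dispersion
    clipped = 0
    for pi, pop in pops.iterrows():
        dfrac = pop["day"] / d_max
        n_cells = config.cells_per_population
        # shared latent standard normal per block, per cell
        z_blocks = rng.standard_normal((max(len(config.correlated_blocks), 1), n_cells))
        z_own = rng.standard_normal((config.n_genes, n_cells))
        m = _change_law(config.baseline_mean, xi_mu_b, bias[:, pi], xi_mu_d, dfrac)
        c = _change_law(config.eta0, xi_b, bias[:, pi], xi_d, dfrac)
        # solve the log-normal cell-factor CV so that total CV hits the law:
        # CV^2 = 1/m + (1/r)(1+v) + v  with v = CV_f^2
        v = (c ** 2 - 1.0 / m - 1.0 / r) / (1.0 + 1.0 / r)
        bad = v < 0
        clipped += int(bad.sum())
        v = np.clip(v, 0.0, None)
        sig = np.sqrt(np.log1p(v))[:, None]
        z = np.where((block_of >= 0)[:, None],
                     z_blocks[np.clip(block_of, 0, None)], z_own)
        f = np.exp(sig * z - 0.5 * sig ** 2)
        mean_mat = m[:, None] * f
        p_nb = r / (r + mean_mat)
        counts = rng.negative_binomial(r, p_nb)
        count_cols.append(counts)
        for ci in range(n_cells):
            meta_rows.append({
                "cell_id": f"{pop['population_id']}|c{ci:03d}",
                "donor": pop["donor"], "day": int(pop["day"]),
                "dish": pop["dish"], "population_id": pop["population_id"],
            })
    if clipped:
        warnings.warn(f"{clipped} (gene, population) targets below the "
                      "count-noise floor; cell-factor variance clipped to 0")
    metadata = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(np.concatenate(count_cols, axis=1), index=genes,
                          columns=metadata["cell_id"])
    truth = {
        "eta0": config.eta0,
        "baseline_mean": config.baseline_mean,
        "genes": genes,
        "population_ids": list(pops["population_id"]),
        "true_xi_b": xi_b.tolist(),
        "true_xi_d": xi_d.tolist(),
        "true_xi_mu_b": xi_mu_b.tolist(),
        "true_xi_mu_d": xi_mu_d.tolist(),
        "true_bias": bias.tolist(),
        "seed": config.seed,
    }
    return counts, metadata, truth


def generate_ase(counts: pd.DataFrame, metadata: pd.DataFrame,
                 config: SyntheticConfig, truth: dict) -> pd.DataFrame:
    """Allele-specific (cell, gene, SNP, ref, alt) counts for captured cells.

    Each gene gets a fixed random phase per donor (which physical allele is
    the 'reference'), so the signed population bias can be negative while its
    magnitude matches the configured truth. A cell yields ASE reads with
    probability ``ase_capture_rate``; its gene reads are split uniformly over
    the gene's SNPs and allocated ref/alt by a beta-binomial with mean
    allelic fraction ``(1 + phase * b) / 2`` and concentration
    ``bb_concentration``. Ref+alt per SNP partition never exceeds the cell's
    gene count.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = list(counts.index)
    bias = np.asarray(truth["true_bias"], dtype=float)
    pop_index = {p: i for i, p in enumerate(truth["population_ids"])}
    donors = sorted(metadata["donor"].unique())
    donor_index = {d: i for i, d in enumerate(donors)}
    phase = rng.choice([-1.0, 1.0], size=(len(genes), len(donors)))

    cells = metadata["cell_id"].to_numpy()
    missing = set(metadata["population_id"]) - set(pop_index)
    if missing:
        raise KeyError(f"populations missing from truth manifest: {sorted(missing)}")
    cell_pop = metadata["population_id"].map(pop_index).to_numpy()
    cell_donor = metadata["donor"].map(donor_index).to_numpy()
    count_arr = counts.to_numpy()
    n_snps = config.snps_per_gene
    conc = config.bb_concentration

    out_cell, out_gene, out_snp, out_ref, out_alt = [], [], [], [], []
    for gi, gene in enumerate(genes):
        captured = rng.random(len(cells)) < config.ase_capture_rate
        idx = np.nonzero(captured & (count_arr[gi] > 0))[0]
        if idx.size == 0:
            continue
        totals = count_arr[gi, idx].astype(np.int64)
        f_ref = 0.5 * (1.0 + phase[gi, cell_donor[idx]] * bias[gi, cell_pop[idx]])
        # uniform split of the gene's reads over its SNPs
        snp_reads = rng.multinomial(totals, np.full(n_snps, 1.0 / n_snps))
        # beta-binomial via its beta-mixture representation, vectorised per SNP
        for si in range(n_snps):
            n_reads = snp_reads[:, si]
            p_cell = np.empty(idx.size)
            interior = (f_ref > 0.0) & (f_ref < 1.0)
            p_cell[~interior] = f_ref[~interior]  # degenerate: fixed allele
            if interior.any():
                fi = f_ref[interior]
                p_cell[interior] = rng.beta(fi * conc, (1.0 - fi) * conc)
            ref = rng.binomial(n_reads, p_cell)
            keep = n_reads > 0
            out_cell.append(cells[idx][keep])
            out_gene.append(np.full(keep.sum(), gene, dtype=object))
            out_snp.append(np.full(keep.sum(), f"{gene}_snp{si}", dtype=object))
            out_ref.append(ref[keep])
            out_alt.append((n_reads - ref)[keep])
    if not out_cell:
        return pd.DataFrame(columns=["cell_id", "gene", "snp_id",
                                     "ref_count", "alt_count"])
    ase = pd.DataFrame({
        "cell_id": np.concatenate(out_cell),
        "gene": np.concatenate(out_gene),
        "snp_id": np.concatenate(out_snp),
        "ref_count": np.concatenate(out_ref).astype(int),
        "alt_count": np.concatenate(out_alt).astype(int),
    })
    return ase.sort_values(["gene", "cell_id", "snp_id"],
                           kind="stable").reset_index(drop=True)


@dataclass
class BrainConfig:
    """Ground truth for the brain-like (cell type x age) generator.

    ``populations`` lists the (cell_type, age) groups; the defaults mirror a
    perinatal-to-adult design with an astrocyte lineage (aIPC at P0 maturing
    to astro at P42), a neuron lineage (NI at P0, NII at P42) and
    oligodendrocytes at both ages. ``block_rho`` maps population ->
    within-block target Pearson correlation of log expression; genes outside
    a block stay independent.
    """

    n_genes: int = 60
    cells_per_population: int = 200
    baseline_mean: float = 400.0
    log_sd: float = 0.6               # SD of the latent log-normal expression factor
    populations: tuple = (("aIPC", "P0"), ("astro", "P42"),
                          ("NI", "P0"), ("NII", "P42"),
                          ("oligo", "P0"), ("oligo", "P42"))
    correlated_blocks: list = field(default_factory=lambda: [list(range(0, 10)),
                                                             list(range(10, 20))])
    block_rho: dict = field(default_factory=lambda: {
        # astrocyte lineage loses correlation with age, neurons gain it
        ("aIPC", "P0"): [0.6, 0.0], ("astro", "P42"): [0.2, 0.0],
        ("NI", "P0"): [0.0, 0.2], ("NII", "P42"): [0.0, 0.6],
        ("oligo", "P0"): [0.3, 0.3], ("oligo", "P42"): [0.3, 0.3],
    })
    cell_types: tuple = ("aIPC", "astro", "NI", "NII", "oligo")
    seed: int = 0


def generate_brain_like(config: BrainConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Counts and metadata for the cell-type x age design.

    Expression is log-normal around ``baseline_mean`` with Poisson count
    sampling; genes within a correlated block load on a shared per-cell
    latent factor with loading sqrt(rho), so the log-expression correlation
    of two block members approaches the configured rho. The truth manifest
    records per-population rho so MI-change ground truth (which blocks gain
    or lose correlation between ages) is recoverable.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"bgene{g:03d}" for g in range(config.n_genes)]
    for ct, age in config.populations:
        if ct not in config.cell_types:
            raise ValueError(f"unknown cell type label: {ct!r}")
    block_of = np.full(config.n_genes, -1)
    for bi, members in enumerate(config.correlated_blocks):
        for g in members:
            if g < config.n_genes:  # default blocks may exceed a tiny gene set
                block_of[g] = bi

    meta_rows, cols = [], []
    for ct, age in config.populations:
        pop_id = f"{ct}|{age}"
        n_cells = config.cells_per_population
        rhos = np.asarray(config.block_rho.get((ct, age),
                          [0.0] * max(len(config.correlated_blocks), 1)), dtype=float)
        z_blocks = rng.standard_normal((max(len(config.correlated_blocks), 1), n_cells))
        eps = rng.standard_normal((config.n_genes, n_cells))
        load = np.where(block_of >= 0, np.sqrt(rhos[np.clip(block_of, 0, None)]), 0.0)
        z = load[:, None] * z_blocks[np.clip(block_of, 0, None)] \
            + np.sqrt(1.0 - load ** 2)[:, None] * eps
        log_mean = np.log(config.baseline_mean) + config.log_sd * z \
            - 0.5 * config.log_sd ** 2
        counts = rng.poisson(np.exp(log_mean))
        cols.append(counts)
        for ci in range(n_cells):
            meta_rows.append({"cell_id": f"{pop_id}|c{ci:03d}", "cell_type": ct,
                              "age": age, "population_id": pop_id,
                              "donor": "mouse0", "day": 0, "dish": "na"})
    metadata = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(np.concatenate(cols, axis=1), index=genes,
                          columns=metadata["cell_id"])
    truth = {
        "genes": genes,
        "blocks": [list(map(int, b)) for b in config.correlated_blocks],
        "block_rho": {f"{ct}|{age}": list(map(float, np.atleast_1d(r)))
                      for (ct, age), r in config.block_rho.items()},
        "seed": config.seed,
    }
    return counts, metadata, truth


def write_dataset(outdir, counts: pd.DataFrame, metadata: pd.DataFrame,
                  truth: dict, ase: pd.DataFrame | None = None) -> None:
    """Write counts (MTX + gene/cell lists), metadata, ASE and truth to disk."""
    import os
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    os.makedirs(outdir, exist_ok=True)
    sio.mmwrite(os.path.join(outdir, "counts.mtx"),
                csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(os.path.join(outdir, "genes.tsv"),
                                   sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(os.path.join(outdir, "cells.tsv"),
                                     sep="\t", index=False, header=False)
    metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    if ase is not None:
        ase.to_csv(os.path.join(outdir, "ase.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
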