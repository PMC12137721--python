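"""Per-(gene, population) observables of expression variability.

Four quantities characterise how a gene behaves in a cell population
(cells sharing donor, differentiation day and dish, or cell type and age):

* **genetic noise** ``eta = sigma / mu`` — the coefficient of variation of
  expression across the cells of the population;
* **genetic entropy** ``h = sum_x p(x) * log(p(x) / q(x))`` — the
  Kullback–Leibler divergence (nats) between the population's expression
  distribution ``p`` and the pooled distribution ``q`` of the same gene over
  all cells of all populations;
* **expression bias** ``b = (r - a) / (r + a)`` from allele-specific read
  counts, aggregated over SNPs and cells; its magnitude runs from 0 (fully
  biallelic) to 1 (fully monoallelic);
* **mutual information** between two genes, estimated from the Pearson
  correlation of their expression as ``I = -ln(1 - rho^2) / 2`` (nats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "genetic_noise",
    "EntropyBinning",
    "genetic_entropy",
    "expression_bias",
    "mutual_information",
    "compute_all_metrics",
]

#: Lower clamp for 1 - rho^2 in the Gaussian MI estimator.
MI_RHO_CLAMP = 1e-12


def genetic_noise(values: np.ndarray) -> float:
    """Coefficient of variation (sample SD over mean) of an expression vector.

    Parameters
    ----------
    values
        Expression of one gene across the cells of one population
        (any positive-mean units; the CV is scale-invariant).

    Raises
    ------
    ValueError
        If the mean is not strictly positive — such populations are supposed
        to be removed by the expression-level QC filter beforehand.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("genetic noise needs at least two cells")
    mu = v.mean()
    if mu <= 0:
        raise ValueError("genetic noise is undefined for non-positive mean "
                         "(input should have been removed by expression QC)")
    return float(v.std(ddof=1) / mu)


@dataclass
class EntropyBinning:
    """Discretisation shared by a population's ``p`` and the pooled ``q``.

    Equal-frequency bin edges are derived from the pooled distribution of the
    gene over all cells, so that ``q`` is well populated in every bin; a
    pseudocount ``eps`` keeps the divergence finite when a population bin is
    empty in the pool.
    """

    edges: np.ndarray
    q: np.ndarray
    eps: float = 1e-9
    n_pooled: int = 0

    @classmethod
    def from_pooled(cls, pooled: np.ndarray, n_bins: int = 16,
                    eps: float = 1e-9) -> "EntropyBinning":
        """Build equal-frequency bins from the pooled expression values."""
        pooled = np.asarray(pooled, dtype=float)
        if pooled.size == 0:
            raise ValueError("pooled distribution is empty")
        qs = np.linspace(0.0, 1.0, n_bins + 1)
        edges = np.unique(np.quantile(pooled, qs))
        if edges.size < 2:  # constant pool: a single degenerate bin
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
        # open outer bins so every value (incl. future populations) lands somewhere
        inner = edges[1:-1]
        edges = np.concatenate(([-np.inf], inner, [np.inf]))
        counts, _ = np.histogram(pooled, bins=edges)
        q = (counts + eps) / (counts + eps).sum()
        return cls(edges=edges, q=q, eps=eps, n_pooled=pooled.size)

    def histogram(self, values: np.ndarray) -> np.ndarray:
        """Pseudocounted, renormalised probabilities of ``values`` on the bins."""
        counts, _ = np.histogram(np.asarray(values, dtype=float), bins=self.edges)
        p = (counts + self.eps) / (counts + self.eps).sum()
        return p


def genetic_entropy(values: np.ndarray, binning: EntropyBinning) -> float:
    """KL divergence (nats) of a population's expression from the pooled one.

    Always non-negative (Gibbs' inequality, up to pseudocount rounding);
    zero when the binned population distribution equals the pooled one.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty population")
    p = binning.histogram(v)
    h = float(np.sum(p * np.log(p / binning.q)))
    return max(h, 0.0)


def expression_bias(ase: pd.DataFrame,
                    cell_col: str = "cell_id",
                    ref_col: str = "ref_count",
                    alt_col: str = "alt_count") -> tuple[float, float]:
    """Population expression bias from allele-specific counts.

    Each row is one (cell, SNP) observation with reference count ``r`` and
    alternative count ``a``. The single-SNP single-cell bias is
    ``b_ij = (r - a) / (r + a)``; it is averaged per cell with read-count
    weights ``r + a`` over the SNPs of the gene, then unweighted over cells.

    Returns
    -------
    (b_signed, b)
        The signed population bias in [-1, 1] and its magnitude in [0, 1].
        Under random monoallelic expression (different cells silencing
        different alleles) the signed per-cell values cancel, so the
        population magnitude is small even though every cell is monoallelic.
    """
    r = ase[ref_col].to_numpy(dtype=float)
    a = ase[alt_col].to_numpy(dtype=float)
    tot = r + a
    informative = tot > 0
    if not informative.any():
        raise ValueError("no informative reads (bias QC should have removed this)")
    sub = pd.DataFrame({
        "cell": ase[cell_col].to_numpy()[informative],
        "w": tot[informative],
        "wb": (r - a)[informative],  # w * b_ij since b_ij = (r-a)/(r+a)
    })
    per_cell = sub.groupby("cell", sort=False).sum()
    b_cell = per_cell["wb"] / per_cell["w"]
    b_signed = float(b_cell.mean())
    return b_signed, abs(b_signed)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian mutual information ``-ln(1 - rho^2) / 2`` in nats.

    ``rho`` is the Pearson correlation of the two expression vectors;
    ``1 - rho^2`` is clamped at ``MI_RHO_CLAMP`` so perfectly correlated
    inputs give a large finite value instead of infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("mutual information undefined for zero-variance input")
    rho = float(np.corrcoef(x, y)[0, 1])
    return float(-0.5 * np.log(max(1.0 - rho * rho, MI_RHO_CLAMP)))


@dataclass
class MetricsConfig:
    """Knobs for the per-(gene, population) metrics table."""
    n_entropy_bins: int = 16
    entropy_eps: float = 1e-9
    log_base2_offset: float = 1.0  # expression transformed as log2(CPM + offset)


def _log2p(cpm: np.ndarray, offset: float = 1.0) -> np.ndarray:
    return np.log2(cpm + offset)


def compute_all_metrics(cpm: pd.DataFrame,
                        populations: pd.DataFrame,
                        ase: pd.DataFrame | None = None,
                        expression_pass: pd.DataFrame | None = None,
                        bias_pass: pd.DataFrame | None = None,
                        config: MetricsConfig | None = None) -> pd.DataFrame:
    """Assemble the metrics table: one row per (gene, population) passing QC.

    Parameters
    ----------
    cpm
        Gene x cell CPM expression matrix.
    populations
        Per-cell metadata with at least ``cell_id`` and ``population_id``.
    ase
        Optional allele-specific counts (cell_id, gene, snp_id, ref_count,
        alt_count). Bias columns stay NaN for genes or populations without
        passing ASE data.
    expression_pass, bias_pass
        Gene x population boolean QC tables (from :mod:`allelenoise.popqc`).
        When omitted, all (gene, population) pairs are treated as passing.

    Entropy uses a per-gene pooled reference distribution built from the
    cells of all QC-passing populations of that gene, on log2(CPM+1).
    """
    config = config or MetricsConfig()
    meta = populations.set_index("cell_id")
    cells = [c for c in cpm.columns if c in meta.index]
    if len(cells) != cpm.shape[1]:
        missing = cpm.shape[1] - len(cells)
        raise ValueError(f"{missing} cells in the expression matrix have no metadata")
    pop_of = meta.loc[cells, "population_id"]
    pop_cells = {p: list(idx) for p, idx in pop_of.groupby(pop_of).groups.items()}

    ase_groups: dict[tuple, pd.DataFrame] = {}
    if ase is not None and len(ase):
        ase = ase.merge(populations[["cell_id", "population_id"]], on="cell_id")
        for key, grp in ase.groupby(["gene", "population_id"], sort=False):
            ase_groups[key] = grp

    rows = []
    expr = cpm.to_numpy(dtype=float)
    log_expr = _log2p(expr, config.log_base2_offset)
    col_idx = {c: i for i, c in enumerate(cpm.columns)}
    for gi, gene in enumerate(cpm.index):
        passing_pops = []
        for pop, members in pop_cells.items():
            ok = True
            if expression_pass is not None:
                ok = bool(expression_pass.loc[gene, pop])
            if ok:
                passing_pops.append(pop)
        if not passing_pops:
            continue
        pooled = np.concatenate([
            log_expr[gi, [col_idx[c] for c in pop_cells[pop]]] for pop in passing_pops
        ])
        binning = EntropyBinning.from_pooled(pooled, config.n_entropy_bins,
                                             config.entropy_eps)
        for pop in passing_pops:
            idx = [col_idx[c] for c in pop_cells[pop]]
            vals = expr[gi, idx]
            mu = float(vals.mean())
            sigma = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            eta = sigma / mu if mu > 0 else np.nan
            h = genetic_entropy(log_expr[gi, idx], binning)
            row = {
                "gene": gene, "population_id": pop,
                "mu": mu, "sigma": sigma, "eta": eta, "h": h,
                "b_signed": np.nan, "b": np.nan,
                "n_cells": len(idx), "n_bias_cells": 0, "n_bias_reads": 0,
            }
            grp = ase_groups.get((gene, pop))
            if grp is not None:
                tot = grp["ref_count"] + grp["alt_count"]
                row["n_bias_cells"] = int(grp.loc[tot > 0, "cell_id"].nunique())
                row["n_bias_reads"] = int(tot.sum())
                bias_ok = True
                if bias_pass is not None:
                    bias_ok = bool(bias_pass.loc[gene, pop])
                if bias_ok and (tot > 0).any():
                    bs, bm = expression_bias(grp)
                    row["b_signed"], row["b"] = bs, bm
            rows.append(row)
    out = pd.DataFrame(rows, columns=[
        "gene", "population_id", "mu", "sigma", "eta", "h",
        "b_signed", "b", "n_cells", "n_bias_cells", "n_bias_reads"])
    return out
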