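"""Population assembly, CPM normalisation and quality filters.

The analysis unit is the *cell population*: all cells sharing donor,
differentiation day and experimental dish (or cell type and age in the brain
data). Three filters protect the downstream statistics:

* an expression filter — the gene's mean expression in the population must
  reach ``cpm_threshold`` (default 0.2 CPM), because the coefficient of
  variation blows up artificially at very low counts;
* a bias filter — allelic bias is only estimated where at least
  ``min_bias_cells`` cells carry informative reads and the total
  ref+alt read count reaches ``min_bias_reads`` (defaults 5 cells / 25 reads);
* a cell-stage filter — PCA + k-means on log expression, keeping only cells
  whose cluster matches their annotated day of differentiation (removes
  delayed or failed differentiation).

All bounds are inclusive, and each filter is a pure function of its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "QCConfig",
    "cpm_normalize",
    "filter_expression",
    "expression_qc",
    "filter_bias",
    "bias_qc",
    "cluster_cells",
    "build_populations",
]


@dataclass
class QCConfig:
    """Thresholds for the population-level quality filters."""
    cpm_threshold: float = 0.2      # mean CPM floor for noise/entropy
    min_bias_cells: int = 5         # cells with >= 1 informative read
    min_bias_reads: int = 25        # total ref+alt reads in the population
    min_populations: int = 10       # populations needed to fit a gene
    pca_components: int = 10
    kmeans_seed: int = 0
    kmeans_restarts: int = 10


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation of a gene x cell count matrix.

    Each cell (column) is scaled so its values sum to 1e6. Cells with a zero
    total are dropped with a warning — they carry no expression information.
    """
    totals = counts.sum(axis=0)
    empty = totals[totals <= 0].index
    if len(empty):
        warnings.warn(f"dropping {len(empty)} cells with zero total counts")
        counts = counts.drop(columns=empty)
        totals = totals.drop(empty)
    return counts * (1e6 / totals)


def filter_expression(cpm: pd.DataFrame, cells: list, gene,
                      threshold: float = 0.2) -> bool:
    """True iff the gene's mean CPM over the population's cells is >= threshold."""
    if not cells:
        raise ValueError("empty population")
    return bool(cpm.loc[gene, cells].mean() >= threshold)


def expression_qc(cpm: pd.DataFrame, populations: pd.DataFrame,
                  threshold: float = 0.2) -> pd.DataFrame:
    """Gene x population table of the expression filter, computed in one pass."""
    pop_of = populations.set_index("cell_id")["population_id"]
    means = cpm.T.groupby(pop_of.reindex(cpm.columns)).mean().T
    return means >= threshold


def filter_bias(ase: pd.DataFrame, min_cells: int = 5,
                min_reads: int = 25) -> bool:
    """Bias filter for one gene in one population.

    ``ase`` holds that population's (cell, SNP) rows. A cell counts as
    informative when its ref+alt over the gene's SNPs is at least one read.
    """
    if ase is None or len(ase) == 0:
        return False
    tot = ase["ref_count"].to_numpy() + ase["alt_count"].to_numpy()
    cells_with_reads = ase.loc[tot > 0, "cell_id"].nunique()
    return bool(cells_with_reads >= min_cells and tot.sum() >= min_reads)


def bias_qc(ase: pd.DataFrame, populations: pd.DataFrame,
            genes, population_ids,
            min_cells: int = 5, min_reads: int = 25) -> pd.DataFrame:
    """Gene x population table of the bias filter."""
    out = pd.DataFrame(False, index=pd.Index(genes, name="gene"),
                       columns=pd.Index(population_ids, name="population_id"))
    if ase is None or len(ase) == 0:
        return out
    merged = ase.merge(populations[["cell_id", "population_id"]], on="cell_id")
    merged["tot"] = merged["ref_count"] + merged["alt_count"]
    grp = merged[merged["tot"] > 0].groupby(["gene", "population_id"])
    stats = grp.agg(n_cells=("cell_id", "nunique"), n_reads=("tot", "sum"))
    ok = stats[(stats["n_cells"] >= min_cells) & (stats["n_reads"] >= min_reads)]
    for (gene, pop) in ok.index:
        if gene in out.index and pop in out.columns:
            out.loc[gene, pop] = True
    return out


def cluster_cells(cpm: pd.DataFrame, metadata: pd.DataFrame,
                  n_components: int = 10, k: int | None = None,
                  random_state: int = 0, n_init: int = 10) -> pd.Series:
    """Flag cells whose expression cluster disagrees with their annotated day.

    PCA (on log2(CPM+1), cells as samples) followed by k-means with one
    cluster per differentiation day. Each cluster is labelled with the
    majority day of its members (ties broken toward the earliest day); a cell
    passes iff its cluster's label equals its own metadata day.

    Returns a boolean ``cluster_pass`` Series indexed by cell id.
    """
    meta = metadata.set_index("cell_id")
    days = np.sort(meta.loc[cpm.columns, "day"].unique())
    if k is None:
        k = len(days)
    if k > cpm.shape[1]:
        raise ValueError("more clusters requested than cells")
    if len(days) < k:
        raise ValueError(f"need at least {k} distinct days, found {len(days)}")
    X = np.log2(cpm.to_numpy(dtype=float).T + 1.0)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    Z = PCA(n_components=n_components, random_state=random_state).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state).fit(Z)
    labels = km.labels_
    cell_days = meta.loc[cpm.columns, "day"].to_numpy()
    cluster_day = {}
    for c in range(k):
        member_days = cell_days[labels == c]
        if member_days.size == 0:
            cluster_day[c] = days[0]
            continue
        vals, counts = np.unique(member_days, return_counts=True)
        cluster_day[c] = vals[counts == counts.max()].min()  # earliest day on ties
    passed = np.array([cluster_day[c] for c in labels]) == cell_days
    return pd.Series(passed, index=cpm.columns, name="cluster_pass")


def build_populations(metadata: pd.DataFrame,
                      keys: tuple[str, ...] = ("donor", "day", "dish")) -> pd.DataFrame:
    """Attach a ``population_id`` column formed from the grouping keys."""
    meta = metadata.copy()
    meta["population_id"] = meta[list(keys)].astype(str).agg("|".join, axis=1)
    return meta
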