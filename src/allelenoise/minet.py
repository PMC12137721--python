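"""Mutual-information networks across developmental stages.

Pairwise mutual information between genes is estimated from the Pearson
correlation of log expression as ``I = -ln(1 - rho^2) / 2`` (nats). Per
population (cell type x age) an MI matrix is computed; the per-gene mean
change in MI between an early and a late stage ranks genes by how strongly
their coordination with the rest of the transcriptome shifts during
development; genes whose change exceeds twice the median feed a thresholded
graph whose high-degree nodes are the hubs of the rewired network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .metrics import MI_RHO_CLAMP

__all__ = ["mi_matrix", "mi_change", "high_change_genes", "build_network",
           "noise_mi_summary", "MINetwork"]


def mi_matrix(expression: pd.DataFrame, genes: list | None = None,
              log_transform: bool = True) -> pd.DataFrame:
    """Symmetric gene x gene Gaussian MI matrix for one cell population.

    ``expression`` is gene x cell (CPM); MI is estimated on log2(CPM+1).
    Zero-variance genes get NaN rows/columns (MI undefined); the diagonal
    is NaN by convention. ``1 - rho^2`` is clamped so duplicated genes give
    a large finite ceiling instead of infinity.
    """
    sub = expression.loc[genes] if genes is not None else expression
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 cells to estimate correlations")
    X = np.log2(sub.to_numpy(dtype=float) + 1.0) if log_transform \
        else sub.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd <= 1e-12 * (1.0 + np.abs(X.mean(axis=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X)
    mi = -0.5 * np.log(np.clip(1.0 - rho ** 2, MI_RHO_CLAMP, None))
    mi[flat, :] = np.nan
    mi[:, flat] = np.nan
    np.fill_diagonal(mi, np.nan)
    return pd.DataFrame(mi, index=sub.index, columns=sub.index)


def mi_change(matrix_early: pd.DataFrame,
              matrix_late: pd.DataFrame) -> pd.Series:
    """Per-gene mean change in MI with all partners between two stages.

    Genes present in only one stage are excluded (with a warning); the
    change of gene g is the mean over its partners of I_late - I_early.
    """
    common = matrix_early.index.intersection(matrix_late.index)
    dropped = len(matrix_early.index.union(matrix_late.index)) - len(common)
    if dropped:
        warnings.warn(f"{dropped} genes present in only one stage were excluded")
    if len(common) < 2:
        raise ValueError("fewer than 2 genes shared between the two stages")
    diff = matrix_late.loc[common, common] - matrix_early.loc[common, common]
    return diff.mean(axis=1, skipna=True).rename("delta_mi")


def high_change_genes(delta: pd.Series, factor: float = 2.0,
                      direction: str = "both") -> dict:
    """Genes whose MI change exceeds ``factor`` times the median magnitude.

    Returns the ``increase`` set (delta > factor * median |delta|), the
    ``decrease`` set (delta < -factor * median |delta|) and their union as
    ``both`` — development of different lineages shows up on different
    sides, so both directions are reported and the caller selects.
    """
    if direction not in ("both", "increase", "decrease"):
        raise ValueError("direction must be 'both', 'increase' or 'decrease'")
    med = float(delta.abs().median())
    if med == 0:
        empty = set()
        return {"increase": empty, "decrease": empty, "both": empty,
                "threshold": 0.0}
    thr = factor * med
    inc = set(delta.index[delta > thr])
    dec = set(delta.index[delta < -thr])
    out = {"increase": inc, "decrease": dec, "both": inc | dec,
           "threshold": thr}
    return out


def build_network(genes: set, mi: pd.DataFrame, mi_threshold: float | None = None,
                  degree_min: int = 0) -> nx.Graph:
    """Graph over high-change genes with edges where MI reaches the threshold.

    ``mi_threshold`` defaults to the 95th percentile of the off-diagonal MI
    distribution among the selected genes. Nodes whose degree does not
    exceed ``degree_min`` are dropped; surviving nodes carry a ``degree``
    attribute (counted before the degree filter, i.e. edges with other
    high-MI genes).
    """
    genes = [g for g in mi.index if g in genes]
    sub = mi.loc[genes, genes]
    vals = sub.to_numpy()
    offdiag = vals[np.triu_indices(len(genes), k=1)]
    offdiag = offdiag[np.isfinite(offdiag)]
    if mi_threshold is None:
        mi_threshold = float(np.percentile(offdiag, 95)) if offdiag.size else np.inf
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if np.isfinite(vals[i, j]) and vals[i, j] >= mi_threshold:
                g.add_edge(genes[i], genes[j], mi=float(vals[i, j]))
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    drop = [n for n, d in degrees.items() if d <= degree_min]
    g.remove_nodes_from(drop)
    g.graph["mi_threshold"] = float(mi_threshold)
    return g


def noise_mi_summary(metrics: pd.DataFrame,
                     mi_matrices: dict[str, pd.DataFrame]) -> dict:
    """Paired (mean noise, mean MI) per group with a rank association.

    ``metrics`` must carry ``population_id`` and ``eta``; ``mi_matrices``
    maps the same population ids to their MI matrices. With three or more
    groups a Spearman correlation across groups quantifies the (typically
    inverse) noise-MI relationship; with fewer, only the means are returned.
    """
    from scipy import stats

    rows = []
    for pop, mat in mi_matrices.items():
        sub = metrics[metrics["population_id"] == pop]
        vals = mat.to_numpy()
        offdiag = vals[np.triu_indices(len(mat), k=1)]
        rows.append({"group": pop,
                     "mean_eta": float(sub["eta"].mean()),
                     "mean_mi": float(np.nanmean(offdiag))})
    summary = pd.DataFrame(rows)
    out = {"per_group": summary, "spearman_rho": np.nan, "spearman_p": np.nan}
    if len(summary) >= 3:
        rho, p = stats.spearmanr(summary["mean_eta"], summary["mean_mi"])
        out["spearman_rho"], out["spearman_p"] = float(rho), float(p)
    return out


@dataclass
class MINetwork:
    """Bundle of the per-stage MI analysis for one lineage contrast."""
    stage_early: str
    stage_late: str
    mi_early: pd.DataFrame
    mi_late: pd.DataFrame
    delta: pd.Series = field(default=None)
    high_change: dict = field(default_factory=dict)
    graph: nx.Graph = field(default=None)

    @classmethod
    def from_expression(cls, cpm: pd.DataFrame, populations: pd.DataFrame,
                        stage_early: str, stage_late: str,
                        genes: list | None = None, factor: float = 2.0,
                        direction: str = "both",
                        mi_threshold: float | None = None,
                        degree_min: int = 0) -> "MINetwork":
        cells_of = populations.groupby("population_id")["cell_id"].apply(list)
        early = mi_matrix(cpm[cells_of[stage_early]], genes)
        late = mi_matrix(cpm[cells_of[stage_late]], genes)
        delta = mi_change(early, late)
        high = high_change_genes(delta, factor=factor, direction=direction)
        selected = high[direction] if direction != "both" else high["both"]
        graph = build_network(selected, late, mi_threshold=mi_threshold,
                              degree_min=degree_min)
        return cls(stage_early=stage_early, stage_late=stage_late,
                   mi_early=early, mi_late=late, delta=delta,
                   high_change=high, graph=graph)
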