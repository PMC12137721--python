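"""Change-ratio regression and downstream gene-level analyses.

The central model relates a per-population response ``y`` (genetic noise,
genetic entropy or mean expression) of one gene to the population's
expression bias ``b`` and day of differentiation ``d``:

    y = y0 * ((xi_b - 1) * b + 1) * ((xi_d - 1) * d/d_max + 1)

``y0`` is the value at biallelic expression on day 0, ``xi_b`` the ratio of
the response at fully monoallelic (b=1) to fully biallelic (b=0) expression,
and ``xi_d`` the ratio at the last day versus day 0. A ratio above 1 is an
increase, below 1 a decrease. The model is a product of two linear terms,
so it is fitted by nonlinear least squares; Wald p-values test H0: xi = 1.

Built on top of the per-gene fits:

* classification of genes into increase / decrease / no-change;
* a pooled "overall" fit across genes (each gene normalised by its own
  level) for datasets where per-gene statistics are too thin;
* an intrinsic/extrinsic decomposition of the differentiation noise change
  via the log-log regression of noise change on expression change;
* a signed-bias fit that separates monoallelic (b -> +1) from inversely
  monoallelic (b -> -1) expression, for parent-of-origin questions;
* monoallelic gene calling with a Fisher exact imprinted-vs-non-imprinted
  contingency test, and dosage-compensation assessment from the expression
  change ratios (0.5 = uncompensated halving, 1 = full compensation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "NoiseModelFit", "fit_change_model", "fit_all_genes", "classify_changes",
    "overall_fit", "NoiseDecomposition", "decompose_noise",
    "SignedBiasFit", "signed_bias_fit", "call_monoallelic",
    "dosage_assessment", "parental_origin_test",
]


@dataclass
class NoiseModelFit:
    """One gene's fitted change model for one response."""
    gene: str
    response: str
    baseline: float = np.nan
    xi_b: float = np.nan
    xi_d: float = np.nan
    se_baseline: float = np.nan
    se_b: float = np.nan
    se_d: float = np.nan
    p_b: float = np.nan
    p_d: float = np.nan
    n_populations: int = 0
    status: str = "ok"          # ok | failed | degenerate

    def predict(self, b, d, d_max: float = 1.0) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        d = np.asarray(d, dtype=float)
        return self.baseline * ((self.xi_b - 1) * b + 1) \
            * ((self.xi_d - 1) * d / d_max + 1)

    def ci_b(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.xi_b - z * self.se_b, self.xi_b + z * self.se_b

    def ci_d(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.xi_d - z * self.se_d, self.xi_d + z * self.se_d


def _model(X, base, xi_b, xi_d):
    b, dfrac = X
    return base * ((xi_b - 1.0) * b + 1.0) * ((xi_d - 1.0) * dfrac + 1.0)


def fit_change_model(rows: pd.DataFrame, response: str = "eta",
                     bias_col: str = "b", day_col: str = "day",
                     d_max: float | None = None,
                     min_populations: int = 10,
                     gene: str | None = None) -> NoiseModelFit:
    """Fit the multiplicative change model for one gene.

    ``rows`` holds that gene's per-population metrics with the response,
    bias and day columns. Populations with a missing response or bias are
    dropped. Day is rescaled by ``d_max`` (defaults to the largest day in
    the data, so xi_d is the first-to-last-day ratio).

    Returns a :class:`NoiseModelFit`; a rank-deficient design (no variation
    in either covariate) or solver failure sets ``status`` instead of
    raising, mirroring how thin real data behaves.
    """
    gene = gene if gene is not None else str(rows["gene"].iloc[0]) \
        if "gene" in rows else "?"
    sub = rows.dropna(subset=[response, bias_col])
    y = sub[response].to_numpy(dtype=float)
    b = sub[bias_col].to_numpy(dtype=float)
    d = sub[day_col].to_numpy(dtype=float)
    fit = NoiseModelFit(gene=gene, response=response, n_populations=len(sub))
    if len(sub) < min_populations:
        fit.status = "failed"
        return fit
    if d_max is None:
        d_max = d.max() if d.max() > 0 else 1.0
    dfrac = d / d_max
    b_varies = np.ptp(b) > 1e-12
    d_varies = np.ptp(dfrac) > 1e-12
    if not b_varies and not d_varies:
        fit.status = "degenerate"
        return fit
    p0 = (float(np.mean(y)), 1.0, 1.0)
    try:
        popt, pcov = optimize.curve_fit(_model, (b, dfrac), y, p0=p0,
                                        maxfev=10000)
    except (RuntimeError, ValueError):
        fit.status = "failed"
        return fit
    if not np.all(np.isfinite(popt)):
        fit.status = "failed"
        return fit
    fit.baseline, fit.xi_b, fit.xi_d = map(float, popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fit.se_baseline, fit.se_b, fit.se_d = map(float, se)
    dof = max(len(y) - 3, 1)

    def wald_p(est, s):
        if not np.isfinite(s) or s == 0:
            return np.nan
        return float(2 * stats.t.sf(abs(est - 1.0) / s, dof))

    fit.p_b = wald_p(fit.xi_b, fit.se_b) if b_varies else np.nan
    fit.p_d = wald_p(fit.xi_d, fit.se_d) if d_varies else np.nan
    if not b_varies:
        fit.xi_b, fit.se_b = np.nan, np.nan
    if not d_varies:
        fit.xi_d, fit.se_d = np.nan, np.nan
    if fit.baseline <= 0:
        fit.status = "failed"
    return fit


def fit_all_genes(metrics: pd.DataFrame, response: str = "eta",
                  bias_col: str = "b", min_populations: int = 10,
                  d_max: float | None = None) -> pd.DataFrame:
    """Per-gene change-model fits over a metrics table, as a tidy frame."""
    if d_max is None:
        dmx = metrics["day"].max()
        d_max = float(dmx) if dmx > 0 else 1.0
    fits = []
    for gene, grp in metrics.groupby("gene", sort=False):
        f = fit_change_model(grp, response=response, bias_col=bias_col,
                             d_max=d_max, min_populations=min_populations,
                             gene=str(gene))
        fits.append(vars(f))
    return pd.DataFrame(fits)


def classify_changes(fits: pd.DataFrame, alpha: float = 0.05,
                     which: str = "b") -> pd.DataFrame:
    """Label each fitted gene increase / decrease / none for one covariate.

    A gene increases when xi > 1 with p < alpha, decreases when xi < 1 with
    p < alpha. No multiple-testing correction is applied to the calls; a
    Benjamini-Hochberg adjusted column (``p_<which>_bh``) is added for users
    who want it.
    """
    out = fits.copy()
    xi, p = out[f"xi_{which}"], out[f"p_{which}"]
    cls = np.where((p < alpha) & (xi > 1), "increase",
                   np.where((p < alpha) & (xi < 1), "decrease", "none"))
    cls = np.where(out["status"].ne("ok") | p.isna(), "none", cls)
    out[f"class_{which}"] = cls
    valid = out[f"p_{which}"].notna() & out["status"].eq("ok")
    bh = np.full(len(out), np.nan)
    if valid.any():
        bh[valid.to_numpy()] = sm.stats.multipletests(
            out.loc[valid, f"p_{which}"], method="fdr_bh")[1]
    out[f"p_{which}_bh"] = bh
    return out


def overall_fit(metrics: pd.DataFrame, response: str = "eta",
                bias_col: str = "b", normalize: str = "mean",
                min_populations: int = 2) -> NoiseModelFit:
    """Pooled fit across all genes, each normalised by its own level.

    Dividing every gene's response by its gene-level mean (or fitted
    baseline with ``normalize='baseline'``) puts all genes on a common
    scale, so the pooled rows can be fitted with the same parametrization
    even when no single gene has enough populations on its own.
    """
    sub = metrics.dropna(subset=[response, bias_col]).copy()
    if sub[bias_col].nunique() < 2:
        f = NoiseModelFit(gene="__overall__", response=response)
        f.status = "failed"
        return f
    if normalize == "mean":
        norm = sub.groupby("gene")[response].transform("mean")
    elif normalize == "baseline":
        fits = fit_all_genes(sub, response=response, bias_col=bias_col,
                             min_populations=min_populations)
        base = fits.set_index("gene")["baseline"]
        norm = sub["gene"].map(base)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    sub = sub[norm.notna() & (norm > 0)]
    sub[response] = sub[response] / norm[norm.notna() & (norm > 0)]
    return fit_change_model(sub, response=response, bias_col=bias_col,
                            min_populations=min_populations,
                            gene="__overall__")


@dataclass
class NoiseDecomposition:
    """Intrinsic/extrinsic split of the differentiation noise change."""
    slope: float
    intercept: float
    slope_se: float
    per_gene: pd.DataFrame           # gene, total, intrinsic, extrinsic
    median_intrinsic: float = np.nan
    median_extrinsic: float = np.nan
    median_total: float = np.nan


def decompose_noise(eta_fits: pd.DataFrame,
                    mu_fits: pd.DataFrame) -> NoiseDecomposition:
    """Split each gene's noise change over differentiation into parts.

    Lower expression raises intrinsic noise, so across genes log(xi_eta_d)
    is linearly related to log(xi_mu_d). The fitted slope defines the
    intrinsic component ``(xi_mu_d)^slope`` — the noise change explained by
    the gene's own expression change — and the extrinsic component is the
    remainder, ``xi_eta_d / intrinsic``; the two multiply back to the total
    exactly.
    """
    merged = eta_fits.merge(mu_fits, on="gene", suffixes=("_eta", "_mu"))
    merged = merged[(merged["status_eta"] == "ok") & (merged["status_mu"] == "ok")]
    merged = merged[(merged["xi_d_eta"] > 0) & (merged["xi_d_mu"] > 0)]
    if len(merged) < 3:
        raise ValueError("need at least 3 genes with valid fits to decompose")
    lx = np.log(merged["xi_d_mu"].to_numpy())
    ly = np.log(merged["xi_d_eta"].to_numpy())
    ols = sm.OLS(ly, sm.add_constant(lx)).fit()
    intercept, slope = ols.params
    intrinsic = merged["xi_d_mu"] ** slope
    extrinsic = merged["xi_d_eta"] / intrinsic
    per_gene = pd.DataFrame({
        "gene": merged["gene"],
        "total": merged["xi_d_eta"],
        "intrinsic": intrinsic,
        "extrinsic": extrinsic,
    })
    return NoiseDecomposition(
        slope=float(slope), intercept=float(intercept),
        slope_se=float(ols.bse[1]), per_gene=per_gene.reset_index(drop=True),
        median_intrinsic=float(intrinsic.median()),
        median_extrinsic=float(extrinsic.median()),
        median_total=float(merged["xi_d_eta"].median()),
    )


@dataclass
class SignedBiasFit:
    """Separate change ratios toward b=+1 and b=-1 monoallelic expression."""
    gene: str
    baseline: float = np.nan
    xi_plus: float = np.nan          # change at fully monoallelic b_signed=+1
    xi_minus: float = np.nan         # change at inversely monoallelic b_signed=-1
    xi_d: float = np.nan
    se_plus: float = np.nan
    se_minus: float = np.nan
    p_equal: float = np.nan          # H0: xi_plus == xi_minus
    n_populations: int = 0
    status: str = "ok"


def _signed_model(X, base, xi_p, xi_m, xi_d):
    bs, dfrac = X
    bp = np.clip(bs, 0, None)
    bm = np.clip(-bs, 0, None)
    return base * ((xi_p - 1.0) * bp + (xi_m - 1.0) * bm + 1.0) \
        * ((xi_d - 1.0) * dfrac + 1.0)


def signed_bias_fit(rows: pd.DataFrame, response: str = "eta",
                    bias_col: str = "b_signed", day_col: str = "day",
                    d_max: float | None = None,
                    min_populations: int = 10,
                    gene: str | None = None) -> SignedBiasFit:
    """Fit the change model on the *signed* bias.

    If the noise increase were a parent-of-origin effect, the change toward
    b=+1 would differ from the change toward b=-1; the Wald test on
    xi_plus - xi_minus quantifies that. Data with only one sign of bias is
    flagged degenerate rather than fitted.
    """
    gene = gene if gene is not None else (str(rows["gene"].iloc[0])
                                          if "gene" in rows else "?")
    sub = rows.dropna(subset=[response, bias_col])
    fit = SignedBiasFit(gene=gene, n_populations=len(sub))
    y = sub[response].to_numpy(dtype=float)
    bs = sub[bias_col].to_numpy(dtype=float)
    d = sub[day_col].to_numpy(dtype=float)
    if len(sub) < min_populations:
        fit.status = "failed"
        return fit
    if not ((bs > 0).any() and (bs < 0).any()):
        fit.status = "degenerate"
        return fit
    if d_max is None:
        d_max = d.max() if d.max() > 0 else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _signed_model, (bs, d / d_max), y,
            p0=(float(np.mean(y)), 1.0, 1.0, 1.0), maxfev=20000)
    except (RuntimeError, ValueError):
        fit.status = "failed"
        return fit
    fit.baseline, fit.xi_plus, fit.xi_minus, fit.xi_d = map(float, popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fit.se_plus, fit.se_minus = float(se[1]), float(se[2])
    diff = fit.xi_plus - fit.xi_minus
    var_diff = pcov[1, 1] + pcov[2, 2] - 2 * pcov[1, 2]
    if var_diff > 0 and np.isfinite(var_diff):
        dof = max(len(y) - 4, 1)
        fit.p_equal = float(2 * stats.t.sf(abs(diff) / np.sqrt(var_diff), dof))
    return fit


def call_monoallelic(metrics: pd.DataFrame, annotations: pd.DataFrame,
                     b_threshold: float = 0.5, min_pops: int = 5,
                     rule: str = "median") -> tuple[pd.DataFrame, dict]:
    """Call each gene biallelic/monoallelic and test the imprinted excess.

    A gene needs bias estimates in at least ``min_pops`` populations.
    ``rule='median'`` calls a gene monoallelic when its median population
    bias magnitude reaches ``b_threshold``; ``rule='any'`` when any
    population does. ``annotations`` maps gene -> annotation
    {imprinted, predicted, non-imprinted} and optional parental status.

    Returns the per-gene call table and a Fisher exact test of the 2x2
    table imprinted-vs-non-imprinted x monoallelic-vs-biallelic (predicted
    genes are grouped with the non-imprinted, mirroring how thin the
    evidence for predicted imprinting is).
    """
    ann = annotations.set_index("gene")
    rows = []
    for gene, grp in metrics.dropna(subset=["b"]).groupby("gene"):
        if len(grp) < min_pops:
            continue
        frac_mono = float((grp["b"] >= b_threshold).mean())
        if rule == "median":
            mono = bool(grp["b"].median() >= b_threshold)
        elif rule == "any":
            mono = bool((grp["b"] >= b_threshold).any())
        else:
            raise ValueError(f"unknown calling rule {rule!r}")
        a = ann["annotation"].get(gene, "non-imprinted")
        rows.append({
            "gene": gene,
            "call": "monoallelic" if mono else "biallelic",
            "frac_mono_populations": frac_mono,
            "n_populations": len(grp),
            "annotation": a,
            "parental": ann["parental"].get(gene, "unknown")
            if "parental" in ann else "unknown",
        })
    calls = pd.DataFrame(rows)
    if calls.empty:
        raise ValueError("no gene has enough populations with bias estimates")
    imprinted = calls["annotation"].eq("imprinted")
    if imprinted.all() or (~imprinted).all():
        raise ValueError("need both imprinted and non-imprinted genes for the test")
    mono = calls["call"].eq("monoallelic")
    table = [[int((imprinted & mono).sum()), int((imprinted & ~mono).sum())],
             [int((~imprinted & mono).sum()), int((~imprinted & ~mono).sum())]]
    odds, p = stats.fisher_exact(table)
    contingency = {"table": table, "odds_ratio": float(odds),
                   "fisher_p": float(p)}
    return calls, contingency


def dosage_assessment(mu_fits: pd.DataFrame) -> dict:
    """Summarise expression change ratios against the dosage references.

    An uncompensated loss of one allele halves expression (xi_mu_b = 0.5);
    full dosage compensation leaves it unchanged (xi_mu_b = 1). Genes with
    xi_mu_b > 0.5 express beyond simple halving, i.e. show at least partial
    compensation.
    """
    ok = mu_fits[mu_fits["status"] == "ok"].copy()
    ok["beyond_halving"] = ok["xi_b"] > 0.5
    return {
        "per_gene": ok[["gene", "xi_b", "se_b", "p_b", "beyond_halving"]]
        .rename(columns={"xi_b": "xi_mu_b"}).reset_index(drop=True),
        "median_xi_mu_b": float(ok["xi_b"].median()) if len(ok) else np.nan,
        "n_beyond_halving": int(ok["beyond_halving"].sum()),
        "n_genes": int(len(ok)),
        "n_failed": int((mu_fits["status"] != "ok").sum()),
    }


def parental_origin_test(fits: pd.DataFrame,
                         annotations: pd.DataFrame) -> dict:
    """Rank-sum comparison of noise change between maternally and paternally
    imprinted genes (a parent-of-origin effect would separate the groups)."""
    ann = annotations.set_index("gene")["parental"]
    sub = fits[fits["status"] == "ok"].copy()
    sub["parental"] = sub["gene"].map(ann)
    mat = sub.loc[sub["parental"] == "maternal", "xi_b"].dropna()
    pat = sub.loc[sub["parental"] == "paternal", "xi_b"].dropna()
    if len(mat) < 2 or len(pat) < 2:
        raise ValueError("need at least two genes per parental group")
    stat, p = stats.mannwhitneyu(mat, pat, alternative="two-sided")
    return {"n_maternal": int(len(mat)), "n_paternal": int(len(pat)),
            "median_maternal": float(mat.median()),
            "median_paternal": float(pat.median()),
            "statistic": float(stat), "p_value": float(p)}
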