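"""Telegraph-model stochastic simulation of bi- vs monoallelic expression.

Each gene is a two-state (telegraph) gene-expression system: alleles switch
on with rate ``k_on`` and off with rate ``k_off`` (at most ``N`` active
alleles, N=2 biallelic, N=1 monoallelic), active alleles transcribe at
``k_m``, mRNA decays at ``gamma_m``, is translated at ``k_p`` per molecule,
and protein decays at ``gamma_p``. The mean-field ODEs

    dn/dt = k_on (N - n) - k_off n
    dm/dt = k_m n - gamma_m m
    dp/dt = k_p m - gamma_p p

have the steady state ``n = N k_on/(k_on+k_off)``, ``m = k_m n / gamma_m``,
``p = k_p m / gamma_p``; because all propensities are linear, the exact
stochastic (Gillespie) simulation has the same stationary means, which
serves as an internal oracle. Noise is read off the stationary distribution
across independent simulated cells.

Monoallelic expression with dosage compensation keeps the deterministic
mean fixed (one allele, doubled transcription rate) but concentrates the
allele-switching noise in a single copy, which can only increase the
coefficient of variation — the mechanism by which monoallelic expression
amplifies genetic noise. Regulatory links let the protein count of an
imprinted gene modulate a target's activation (permissive) or inactivation
(repressive) rate, transferring that noise to downstream genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "RateSet", "RegulatoryLink", "Coupling", "SimResult",
    "ode_steady_state", "dosage_compensated_pair",
    "ssa_simulate", "stationary_sample",
    "network_experiment", "rate_ensemble", "RateEnsembleConfig",
]

PERMISSIVE, REPRESSIVE = 0, 1


@dataclass(frozen=True)
class RateSet:
    """Kinetic parameters of one telegraph gene (all rates per unit time)."""
    k_on: float
    k_off: float
    k_m: float
    gamma_m: float
    k_p: float
    gamma_p: float
    N: int = 2

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_m", "gamma_m", "k_p", "gamma_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.N not in (1, 2):
            raise ValueError("N (max active alleles) must be 1 or 2")

    def as_row(self) -> np.ndarray:
        return np.array([self.k_on, self.k_off, self.k_m, self.gamma_m,
                         self.k_p, self.gamma_p], dtype=np.float64)


@dataclass(frozen=True)
class RegulatoryLink:
    """Protein of ``source`` modulates a switching rate of ``target``.

    Permissive links scale the target's activation rate, repressive links
    its inactivation rate, by the Hill-1 ramp blended with identity:
    ``(1 - strength) + strength * p_source / (p_source + half_saturation)``.
    ``strength`` = 0 decouples the genes; 1 applies the full ramp.
    """
    source: int
    target: int
    mode: int                       # PERMISSIVE or REPRESSIVE
    half_saturation: float
    strength: float = 1.0

    def __post_init__(self):
        if self.mode not in (PERMISSIVE, REPRESSIVE):
            raise ValueError("mode must be PERMISSIVE (0) or REPRESSIVE (1)")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")


@dataclass
class Coupling:
    """Coupling of the imprinted gene to its targets in the network experiment."""
    strength: float = 1.0
    half_saturation: float | None = None  # None: imprinted mean protein count


def ode_steady_state(rates: RateSet) -> tuple[float, float, float]:
    """Deterministic steady state (mean active alleles, mRNA, protein)."""
    nbar = rates.N * rates.k_on / (rates.k_on + rates.k_off)
    mbar = rates.k_m * nbar / rates.gamma_m
    pbar = rates.k_p * mbar / rates.gamma_p
    return nbar, mbar, pbar


def dosage_compensated_pair(rates: RateSet) -> tuple[RateSet, RateSet]:
    """Biallelic rate set and its dosage-compensated monoallelic counterpart.

    The monoallelic copy allows a single active allele and doubles the
    transcription rate, so the deterministic means of the two members are
    identical — any noise difference is due to allele number alone.
    """
    if rates.N != 2:
        raise ValueError("dosage pairing starts from a biallelic (N=2) rate set")
    mono = replace(rates, N=1, k_m=2.0 * rates.k_m)
    return rates, mono


# --- Gillespie core (direct method) -------------------------------------
# reactions per gene i: allele on, allele off, transcription, mRNA decay,
# translation, protein decay. Links (L x 5): target, source, mode, K, w.

@njit(cache=True)
def _propensities(rates, Ns, links, n, m, p, a):
    K = rates.shape[0]
    for i in range(K):
        kon, koff = rates[i, 0], rates[i, 1]
        a[6 * i + 0] = kon * (Ns[i] - n[i])
        a[6 * i + 1] = koff * n[i]
        a[6 * i + 2] = rates[i, 2] * n[i]
        a[6 * i + 3] = rates[i, 3] * m[i]
        a[6 * i + 4] = rates[i, 4] * m[i]
        a[6 * i + 5] = rates[i, 5] * p[i]
    for l in range(links.shape[0]):
        tgt = int(links[l, 0])
        src = int(links[l, 1])
        mode = int(links[l, 2])
        Kh = links[l, 3]
        w = links[l, 4]
        ramp = (1.0 - w) + w * p[src] / (p[src] + Kh)
        if mode == 0:
            a[6 * tgt + 0] *= ramp
        else:
            a[6 * tgt + 1] *= ramp


@njit(cache=True)
def _apply(reaction, n, m, p):
    i, r = reaction // 6, reaction % 6
    if r == 0:
        n[i] += 1
    elif r == 1:
        n[i] -= 1
    elif r == 2:
        m[i] += 1
    elif r == 3:
        m[i] -= 1
    elif r == 4:
        p[i] += 1
    else:
        p[i] -= 1


@njit(cache=True)
def _ssa_final(rates, Ns, links, n, m, p, t_end, seed):
    """Advance the state in place to t_end; returns the reaction count."""
    np.random.seed(seed)
    K = rates.shape[0]
    a = np.empty(6 * K)
    t = 0.0
    steps = 0
    while True:
        _propensities(rates, Ns, links, n, m, p, a)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += -math.log(np.random.random()) / a0
        if t > t_end:
            break
        u = np.random.random() * a0
        acc = 0.0
        rxn = 6 * K - 1
        for j in range(6 * K):
            acc += a[j]
            if u < acc:
                rxn = j
                break
        _apply(rxn, n, m, p)
        steps += 1
    return steps


@njit(cache=True)
def _ssa_record(rates, Ns, links, n, m, p, t_end, seed, times, traj):
    """Record the jump trajectory; returns the number of stored points."""
    np.random.seed(seed)
    K = rates.shape[0]
    a = np.empty(6 * K)
    t = 0.0
    cap = times.shape[0]
    count = 0
    times[count] = 0.0
    for i in range(K):
        traj[count, 3 * i] = n[i]
        traj[count, 3 * i + 1] = m[i]
        traj[count, 3 * i + 2] = p[i]
    count += 1
    while count < cap:
        _propensities(rates, Ns, links, n, m, p, a)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += -math.log(np.random.random()) / a0
        if t > t_end:
            break
        u = np.random.random() * a0
        acc = 0.0
        rxn = 6 * K - 1
        for j in range(6 * K):
            acc += a[j]
            if u < acc:
                rxn = j
                break
        _apply(rxn, n, m, p)
        times[count] = t
        for i in range(K):
            traj[count, 3 * i] = n[i]
            traj[count, 3 * i + 1] = m[i]
            traj[count, 3 * i + 2] = p[i]
        count += 1
    return count


@njit(cache=True)
def _ssa_timeavg(rates, Ns, links, n, m, p, burn_in, t_end, seed):
    """Time-weighted first and second moments of (n, m, p) over [burn_in, t_end]."""
    np.random.seed(seed)
    K = rates.shape[0]
    a = np.empty(6 * K)
    mean = np.zeros((K, 3))
    sq = np.zeros((K, 3))
    t = 0.0
    total_w = 0.0
    while True:
        _propensities(rates, Ns, links, n, m, p, a)
        a0 = a.sum()
        if a0 <= 0.0:
            dt = t_end - t
            t_next = t_end
        else:
            dt = -math.log(np.random.random()) / a0
            t_next = t + dt
        lo = t if t > burn_in else burn_in
        hi = t_next if t_next < t_end else t_end
        if hi > lo:
            w = hi - lo
            total_w += w
            for i in range(K):
                mean[i, 0] += w * n[i]
                mean[i, 1] += w * m[i]
                mean[i, 2] += w * p[i]
                sq[i, 0] += w * n[i] * n[i]
                sq[i, 1] += w * m[i] * m[i]
                sq[i, 2] += w * p[i] * p[i]
        if a0 <= 0.0 or t_next >= t_end:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        rxn = 6 * K - 1
        for j in range(6 * K):
            acc += a[j]
            if u < acc:
                rxn = j
                break
        _apply(rxn, n, m, p)
    if total_w > 0:
        mean /= total_w
        sq /= total_w
    return mean, sq


def _pack(rate_sets: list[RateSet], links: list[RegulatoryLink]):
    rates = np.stack([r.as_row() for r in rate_sets])
    Ns = np.array([r.N for r in rate_sets], dtype=np.int64)
    if links:
        larr = np.array([[l.target, l.source, l.mode, l.half_saturation,
                          l.strength] for l in links], dtype=np.float64)
    else:
        larr = np.zeros((0, 5), dtype=np.float64)
    return rates, Ns, larr


def _initial_state(rate_sets: list[RateSet], rng: np.random.Generator):
    """Start near the deterministic steady state to shorten burn-in."""
    n = np.empty(len(rate_sets), dtype=np.int64)
    m = np.empty(len(rate_sets), dtype=np.int64)
    p = np.empty(len(rate_sets), dtype=np.int64)
    for i, r in enumerate(rate_sets):
        nbar, mbar, pbar = ode_steady_state(r)
        n[i] = rng.binomial(r.N, r.k_on / (r.k_on + r.k_off))
        m[i] = rng.poisson(mbar)
        p[i] = rng.poisson(pbar)
    return n, m, p


def default_burn_in(rate_sets: list[RateSet]) -> float:
    """Ten times the slowest relaxation time over all genes and channels."""
    slowest = min(min(r.gamma_m, r.gamma_p, r.k_on + r.k_off)
                  for r in rate_sets)
    return 10.0 / slowest


def ssa_simulate(rates: RateSet | list[RateSet], t_end: float, seed: int,
                 links: list[RegulatoryLink] | None = None,
                 max_events: int = 2_000_000,
                 initial: tuple | None = None):
    """Exact stochastic trajectory of one or several coupled telegraph genes.

    Returns ``(times, states)`` where ``states`` has one row per jump and
    columns (n, m, p) per gene. Deterministic given ``seed``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rate_sets = [rates] if isinstance(rates, RateSet) else list(rates)
    arr, Ns, larr = _pack(rate_sets, links or [])
    if initial is None:
        rng = np.random.default_rng(seed)
        n, m, p = _initial_state(rate_sets, rng)
    else:
        n, m, p = (np.asarray(x, dtype=np.int64).copy() for x in initial)
    times = np.empty(max_events)
    traj = np.empty((max_events, 3 * len(rate_sets)), dtype=np.int64)
    count = _ssa_record(arr, Ns, larr, n, m, p, t_end, seed % (2 ** 31), times, traj)
    if count == max_events:
        warnings.warn("trajectory truncated at max_events before t_end")
    return times[:count].copy(), traj[:count].copy()


def ssa_time_average(rates: RateSet | list[RateSet], t_end: float, seed: int,
                     burn_in: float = 0.0,
                     links: list[RegulatoryLink] | None = None,
                     initial: tuple | None = None):
    """Time-averaged means and variances of (n, m, p) on [burn_in, t_end]."""
    rate_sets = [rates] if isinstance(rates, RateSet) else list(rates)
    arr, Ns, larr = _pack(rate_sets, links or [])
    if initial is None:
        rng = np.random.default_rng(seed)
        n, m, p = _initial_state(rate_sets, rng)
    else:
        n, m, p = (np.asarray(x, dtype=np.int64).copy() for x in initial)
    mean, sq = _ssa_timeavg(arr, Ns, larr, n, m, p, burn_in, t_end,
                            seed % (2 ** 31))
    var = np.clip(sq - mean ** 2, 0.0, None)
    return mean, var


def stationary_sample(rate_sets: list[RateSet], n_cells: int, seed: int,
                      links: list[RegulatoryLink] | None = None,
                      burn_in: float | None = None) -> np.ndarray:
    """One stationary (n, m, p) snapshot per independent simulated cell.

    Cells are independent realisations (a dissociated-cell measurement):
    each starts near the deterministic steady state and is burnt in for
    ``burn_in`` time units (default :func:`default_burn_in`) before its
    state is read. Returns an array of shape (n_cells, 3 * n_genes).
    """
    arr, Ns, larr = _pack(rate_sets, links or [])
    if burn_in is None:
        burn_in = default_burn_in(rate_sets)
    rng = np.random.default_rng(seed)
    out = np.empty((n_cells, 3 * len(rate_sets)), dtype=np.int64)
    for c in range(n_cells):
        n, m, p = _initial_state(rate_sets, rng)
        _ssa_final(arr, Ns, larr, n, m, p, burn_in,
                   int(rng.integers(0, 2 ** 31)))
        for i in range(len(rate_sets)):
            out[c, 3 * i] = n[i]
            out[c, 3 * i + 1] = m[i]
            out[c, 3 * i + 2] = p[i]
    return out


@dataclass
class SimResult:
    """Noise-change estimates of one bi- vs monoallelic network experiment."""
    roles: list
    mean_p_bi: np.ndarray
    mean_p_mono: np.ndarray
    cv_p_bi: np.ndarray
    cv_p_mono: np.ndarray
    cv_m_bi: np.ndarray
    cv_m_mono: np.ndarray
    xi_sim: np.ndarray               # CV_p(mono) / CV_p(bi) per gene
    xi_sim_se: np.ndarray
    xi_sim_mrna: np.ndarray
    n_cells: int = 0
    burn_in: float = 0.0
    seed: int = 0

    def as_dict(self) -> dict:
        return {role: {"xi_sim": float(self.xi_sim[i]),
                       "se": float(self.xi_sim_se[i]),
                       "mean_p_bi": float(self.mean_p_bi[i]),
                       "mean_p_mono": float(self.mean_p_mono[i])}
                for i, role in enumerate(self.roles)}


def _cv(x: np.ndarray) -> float:
    mu = x.mean()
    return float(x.std(ddof=1) / mu) if mu > 0 else np.nan


def network_experiment(imprinted: RateSet,
                       expressed: RateSet | None = None,
                       repressed: RateSet | None = None,
                       coupling: Coupling | None = None,
                       n_cells: int = 500, seed: int = 0,
                       burn_in: float | None = None,
                       n_boot: int = 100) -> SimResult:
    """Noise change from bi- to dosage-compensated monoallelic expression.

    Simulates ``n_cells`` independent cells under the biallelic imprinted
    gene and under its dosage-compensated monoallelic counterpart, with
    optional permissively and repressively regulated target genes, and
    reports the protein-level noise change ratio ``xi_sim`` per gene with a
    bootstrap Monte-Carlo standard error.
    """
    if n_cells < 30:
        warnings.warn("fewer than 30 cells per condition gives an unstable "
                      "CV estimate")
    coupling = coupling or Coupling()
    bi, mono = dosage_compensated_pair(imprinted)
    _, _, p_imp = ode_steady_state(imprinted)
    K_half = coupling.half_saturation if coupling.half_saturation is not None \
        else max(p_imp, 1.0)

    roles, targets, links = ["imprinted"], [], []
    if expressed is not None:
        links.append(RegulatoryLink(source=0, target=len(roles), mode=PERMISSIVE,
                                    half_saturation=K_half,
                                    strength=coupling.strength))
        roles.append("expressed")
        targets.append(expressed)
    if repressed is not None:
        links.append(RegulatoryLink(source=0, target=len(roles), mode=REPRESSIVE,
                                    half_saturation=K_half,
                                    strength=coupling.strength))
        roles.append("repressed")
        targets.append(repressed)

    samples = {}
    for mode_name, imp_rates in (("bi", bi), ("mono", mono)):
        gene_sets = [imp_rates] + targets
        if burn_in is None:
            bi_time = default_burn_in(gene_sets)
        else:
            bi_time = burn_in
        mode_seed = (seed * 2 + (0 if mode_name == "bi" else 1)) % (2 ** 31)
        samples[mode_name] = stationary_sample(gene_sets, n_cells, mode_seed,
                                               links=links, burn_in=bi_time)

    G = len(roles)
    p_bi = samples["bi"][:, 2::3]
    p_mono = samples["mono"][:, 2::3]
    m_bi = samples["bi"][:, 1::3]
    m_mono = samples["mono"][:, 1::3]
    cv_p_bi = np.array([_cv(p_bi[:, i]) for i in range(G)])
    cv_p_mono = np.array([_cv(p_mono[:, i]) for i in range(G)])
    cv_m_bi = np.array([_cv(m_bi[:, i]) for i in range(G)])
    cv_m_mono = np.array([_cv(m_mono[:, i]) for i in range(G)])
    xi = cv_p_mono / cv_p_bi
    xi_m = cv_m_mono / cv_m_bi

    rng = np.random.default_rng(seed + 12345)
    boots = np.empty((n_boot, G))
    for bidx in range(n_boot):
        ib = rng.integers(0, n_cells, n_cells)
        im = rng.integers(0, n_cells, n_cells)
        for g in range(G):
            boots[bidx, g] = _cv(p_mono[im, g]) / _cv(p_bi[ib, g])
    se = boots.std(axis=0, ddof=1)

    return SimResult(roles=roles,
                     mean_p_bi=p_bi.mean(axis=0), mean_p_mono=p_mono.mean(axis=0),
                     cv_p_bi=cv_p_bi, cv_p_mono=cv_p_mono,
                     cv_m_bi=cv_m_bi, cv_m_mono=cv_m_mono,
                     xi_sim=xi, xi_sim_se=se, xi_sim_mrna=xi_m,
                     n_cells=n_cells, burn_in=bi_time, seed=seed)


def default_target_rates() -> dict[str, RateSet]:
    """Default kinetics of the regulated target genes.

    Both targets switch fast and express highly, so their own intrinsic
    noise is small and the slow protein channel (gamma_p = 0.2) passes the
    imprinted regulator's fluctuations through — the regime in which noise
    transfer is visible. The repressed target is inactivation-dominated
    (k_off >> k_on), where the repressive ramp on k_off has the most
    leverage; its transferred noise varies strongly across imprinted-gene
    rate sets.
    """
    return {
        "expressed": RateSet(k_on=2.0, k_off=2.0, k_m=25.0, gamma_m=1.0,
                             k_p=4.0, gamma_p=0.2, N=2),
        "repressed": RateSet(k_on=2.0, k_off=6.0, k_m=40.0, gamma_m=1.0,
                             k_p=4.0, gamma_p=0.2, N=2),
    }


@dataclass
class RateEnsembleConfig:
    """Log-uniform sampling ranges for the rate ensemble.

    Switching rates span slow (bursty) to fast (near-constitutive) regimes
    relative to the mRNA lifetime; transcription and translation rates are
    sampled through target mean molecule numbers so that every draw has
    physically sensible copy numbers.
    """
    k_on: tuple = (0.1, 1.0)
    k_off: tuple = (0.1, 1.0)
    gamma_m: tuple = (0.5, 2.0)
    gamma_p: tuple = (0.2, 1.0)
    mean_mrna: tuple = (5.0, 50.0)       # target biallelic mean mRNA
    mean_protein: tuple = (50.0, 500.0)  # target biallelic mean protein

    def __post_init__(self):
        for name in ("k_on", "k_off", "gamma_m", "gamma_p",
                     "mean_mrna", "mean_protein"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}")


def rate_ensemble(config: RateEnsembleConfig | None = None,
                  n_sets: int = 50, seed: int = 0) -> list[RateSet]:
    """Reproducible ensemble of biallelic rate sets spanning the configured
    kinetic regimes."""
    config = config or RateEnsembleConfig()
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    rng = np.random.default_rng(seed)

    def draw(lohi):
        lo, hi = lohi
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    out = []
    for _ in range(n_sets):
        k_on, k_off = draw(config.k_on), draw(config.k_off)
        gamma_m, gamma_p = draw(config.gamma_m), draw(config.gamma_p)
        mbar, pbar = draw(config.mean_mrna), draw(config.mean_protein)
        nbar = 2.0 * k_on / (k_on + k_off)
        k_m = mbar * gamma_m / nbar
        k_p = pbar * gamma_p / mbar
        out.append(RateSet(k_on=k_on, k_off=k_off, k_m=k_m, gamma_m=gamma_m,
                           k_p=k_p, gamma_p=gamma_p, N=2))
    return out
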