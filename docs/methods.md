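# Methods

## Scientific setting

Most mammalian genes are expressed from both alleles. Genomic imprinting —
and more broadly any monoallelic expression — silences one copy, leaving a
single stochastic transcription unit where two used to average each other
out. This package quantifies the consequence for expression variability in
single-cell data and predicts it from first principles with a stochastic
gene-expression model.

The unit of analysis is the **cell population**: all cells sharing donor,
day of differentiation and experimental dish (iPSC-style designs), or cell
type and age (brain-style designs). Per gene and population, four
observables are computed:

* **genetic noise** η = σ/μ, the coefficient of variation of CPM expression
  across the population's cells;
* **genetic entropy** h = Σₓ p(x)·ln(p(x)/q(x)), the Kullback–Leibler
  divergence (nats) between the population's expression distribution p and
  the pooled distribution q of the same gene over all cells of all
  populations;
* **expression bias** b, from allele-specific read counts at heterozygous
  SNPs: per SNP and cell b_ij = (r−a)/(r+a), read-count-weighted mean over
  SNPs per cell, unweighted mean over cells; the signed value lives in
  [−1, 1], the magnitude in [0, 1] (0 biallelic, 1 monoallelic);
* **mutual information** between two genes, I = −ln(1−ρ²)/2 in nats, with
  ρ the Pearson correlation of log₂(CPM+1) expression.

## Change-ratio regression

The response y ∈ {η, h, μ} of one gene across its populations is modelled
multiplicatively in the bias b and the rescaled day d/d_max:

    y = y₀ · ((ξ_b − 1)·b + 1) · ((ξ_d − 1)·d/d_max + 1)

ξ_b is the ratio of the response at fully monoallelic to fully biallelic
expression; ξ_d the last-day to day-0 ratio; values above (below) 1 are
increases (decreases). Although each factor is linear, the product is not,
so the model is fitted by nonlinear least squares (`scipy.curve_fit`,
initialised at y₀ = mean response, ξ = 1). Wald p-values on the
Jacobian-based covariance test H₀: ξ = 1 with n−3 degrees of freedom.
Genes need at least 10 populations (configurable); rank-deficient designs
and non-convergence are flagged, not raised.

Why least squares on the printed form rather than a log-linear
approximation: the parametrization is exactly invertible at b ∈ {0, 1} and
d ∈ {0, d_max}, so the fitted ξ are directly the ratios of interest; on
synthetic cohorts (500 genes × 60 populations, 60 cells each) the fit
recovers ξ ∈ {0.8, 1.0, 1.4} × {1.0, 1.2} with < 5% median absolute
relative error, 95% CI coverage ≈ 0.92 and a null false-positive rate
≈ 0.05 — adequate calibration without weighting, so no weighting is
applied.

Derived analyses:

* **Overall (pooled) fit** — each gene's response divided by its gene-level
  mean, all rows pooled and fitted once; used where per-gene statistics are
  too thin. Normalising by the fitted baseline instead is available
  (`normalize="baseline"`); the mean is the default because it requires no
  first-pass fit and leaves the ratio structure untouched.
* **Intrinsic/extrinsic decomposition** — across genes, log ξ^η_d is
  regressed on log ξ^μ_d (OLS); intrinsic change = (ξ^μ_d)^slope, extrinsic
  = total/intrinsic, so intrinsic × extrinsic = total identically.
* **Signed-bias fit** — separate ratios toward b = +1 and b = −1 with a
  Wald test of their equality; a parent-of-origin effect would separate
  them. Group-wise, maternally vs paternally imprinted genes are compared
  by a Mann–Whitney rank-sum test on ξ̂_b.
* **Monoallelic calling** — a gene with bias estimates in ≥ 5 populations
  is called monoallelic when its median population bias magnitude ≥ 0.5
  (the per-population threshold used throughout; `rule="any"` is available
  for the more liberal reading). Imprinted vs non-imprinted × mono- vs
  biallelic is tested with Fisher's exact test; genes only *predicted* to
  be imprinted are grouped with the non-imprinted.
* **Dosage assessment** — ξ^μ_b per gene against the reference points 0.5
  (uncompensated halving) and 1 (full compensation); the median and the
  count of genes beyond halving are reported.

No multiple-testing correction is applied to the per-gene increase/decrease
calls; a Benjamini–Hochberg column is emitted alongside for users who want
it.

## Quality control

* CPM normalisation (each cell scaled to 10⁶); cells with zero totals are
  dropped with a warning.
* Expression filter: a (gene, population) enters the noise/entropy analysis
  only if its mean expression ≥ 0.2 CPM (inclusive) — the CV diverges
  artificially at low counts.
* Bias filter: ≥ 5 cells with at least one informative (ref+alt ≥ 1) read
  and ≥ 25 total reads, both inclusive.
* Stage matching: PCA (10 components, on log₂(CPM+1), cells as samples)
  followed by k-means with one cluster per day (10 restarts, fixed seed);
  clusters are labelled by their majority day (ties → earliest day) and
  cells whose cluster label disagrees with their annotated day are removed.
  The transform, component count and k are configurable since different
  datasets warrant different settings.

## Entropy estimation

The KL divergence needs a common discretisation for p and q. Per gene,
equal-frequency bins (default 16) are built from the pooled log₂(CPM+1)
distribution over all QC-passing cells, with open outer bins; both p and q
receive a pseudocount ε = 10⁻⁹ and are renormalised; natural logarithm.
Equal-frequency binning keeps every bin of q populated, so the divergence
is dominated by signal rather than by empty-bin artefacts. The pooled
reference uses QC-passing cells only (the same universe the population
distributions come from). The estimator carries the usual positive
small-sample bias of plug-in KL (order (bins−1)/2n); comparisons are made
across populations of similar size, which this bias affects equally.

## Telegraph-model simulator

Each gene: alleles switch on/off (k_on, k_off; at most N active, N = 2
biallelic, N = 1 monoallelic), active alleles transcribe (k_m), mRNA decays
(γ_m), is translated (k_p), protein decays (γ_p). The mean-field ODEs give
n̄ = N·k_on/(k_on+k_off), m̄ = k_m·n̄/γ_m, p̄ = k_p·m̄/γ_p. The stochastic
realisation is an exact Gillespie (direct-method) simulation of the six
reaction channels per gene, compiled with numba; because all propensities
are linear, its stationary means equal the ODE solution, which serves as a
built-in oracle in the tests.

**Dosage-compensated monoallelic expression** is modelled as N = 1 with
k_m doubled: the deterministic means are then identical to the biallelic
configuration by construction, so any change in the coefficient of
variation is attributable to allele number alone. Concentrating the
allele-switching noise in a single copy can only increase the CV.

**Measurement protocol**: noise is measured on protein counts (the
regulator species) across independent simulated cells — one stationary
snapshot per cell, matching a dissociated-cell single-cell measurement.
Cells are initialised near the deterministic steady state (binomial allele
occupancy, Poisson mRNA/protein) and burnt in for 10/min(γ_m, γ_p,
k_on+k_off) time units before sampling. mRNA-level CVs are reported
alongside. ξ_sim = CV(monoallelic)/CV(biallelic) per gene, with a bootstrap
(100 resamples) Monte-Carlo standard error.

**Regulatory coupling**: the protein count p of the imprinted gene
modulates a target's switching via the Hill-1 ramp blended with identity,
(1−w) + w·p/(p+K); permissive links scale the target's activation rate,
repressive links its inactivation rate. w = 0 decouples the genes exactly;
K defaults to the imprinted gene's mean protein count, where the ramp's
logarithmic sensitivity is 1/2. The functional form is a modelling choice
exposed in the configuration.

**Rate ensemble**: the default ensemble samples log-uniformly
k_on, k_off ∈ [0.1, 1] (relative to an mRNA lifetime of order 1,
i.e. bursty through near-constitutive regimes), γ_m ∈ [0.5, 2],
γ_p ∈ [0.2, 1], and target mean copy numbers m̄ ∈ [5, 50], p̄ ∈ [50, 500],
back-solving k_m and k_p. Under these defaults the ensemble-mean imprinted
noise increase from bi- to compensated monoallelic expression is ≈ 36%,
and every sampled rate set shows an increase.

**Default target genes**: both regulated targets switch fast and express
highly (small intrinsic noise) with a slow protein channel (γ_p = 0.2)
that passes the regulator's slow fluctuations; the repressed target is
inactivation-dominated (k_off = 3·k_on), where the repressive ramp has the
most leverage. With these defaults the expressed target gains ≈ 20–25%
noise and the repressed target ≈ 15–20% with large spread across
imprinted-gene rate sets — noise transfer through repression is strongly
regime-dependent, consistent with its description as highly variable.

## Synthetic data generator

The generator is the package's study-condition emulator, not a convenience
fixture; its defaults encode the emulated designs.

**iPSC-like design** (default): 5 donors × 4 days × 3 dishes = 60
populations, 60 cells each (≈ the per-population cell count of the
emulated differentiation cohort), baseline mean 50 counts/cell,
negative-binomial dispersion 10, baseline noise η₀ = 0.5. Per (gene,
population), the target CV follows the same multiplicative law the
regression fits, evaluated at the configured true ratios and the
population's bias and day. The CV is realised exactly in expectation by a
per-cell log-normal factor whose variance solves
CV² = 1/m + (1/r)(1+v) + v for v; the factor is shared within configured
correlated gene blocks (extrinsic co-variation), otherwise independent per
gene so that CPM normalisation does not cancel it. Mean expression follows
the same law with its own ratios (e.g. ξ^μ_b = 0.5 models uncompensated
halving). Targets below the count-noise floor are clipped to the floor with
a warning.

**Allele-specific counts**: each gene gets a fixed random phase per donor
(which physical allele is "reference"), a cell yields ASE reads with
probability 0.3 (emulating sparse scASE coverage), its gene reads are split
uniformly over 2 SNPs, and ref/alt is drawn beta-binomially (concentration
20) around the allelic fraction (1 + phase·b)/2. Degenerate fractions 0/1
are allocated deterministically. Ref+alt per SNP partition never exceeds
the cell's gene count by construction.

**Brain-like design**: populations (aIPC, P0), (astro, P42), (NI, P0),
(NII, P42), (oligo, P0), (oligo, P42), 200 cells each; log-normal
expression (log-SD 0.6) around a 400-count baseline with Poisson sampling.
Genes in a correlated block load on a shared per-cell latent factor with
loading √ρ, so the log-expression correlation of block members approaches
the configured ρ; the defaults give the astrocyte lineage a correlation
*loss* with age and the neuron lineage a *gain*, with oligodendrocytes
unchanged — the structure the MI-change analysis is designed to detect.

**What the generator does not emulate**: empty droplets, doublets, ambient
RNA, batch effects beyond the population factor, read-level error, UMI
saturation, or any specific real count distribution (the NB + log-normal
family is a modelling choice). Passing tests therefore demonstrate that
the estimators recover the generative law under realistic sampling noise —
not that real data follow that law.

## Mutual-information networks

MI matrices are computed per population on log₂(CPM+1); zero-variance
genes are flagged missing, and 1−ρ² is clamped at 10⁻¹² (a finite ceiling
for duplicated columns). The per-gene MI change between stages is the mean
over partners of I_late − I_early; genes with |change| beyond twice the
median absolute change are "high-change", reported separately for
increases and decreases since different lineages move in different
directions. The network over high-change genes uses an MI edge threshold
defaulting to the 95th percentile of the selected genes' MI distribution
(the printed analyses do not state one), and nodes are filtered by degree.
At desk scale the gene universe is restricted by the caller rather than
chunked; the Gaussian MI estimator has a positive bias floor of order
1/(2(n−1)) at n cells, visible in the independence tests.

## Problem sizes and numerical choices

Test and acceptance runs use 500-gene cohorts at 60 populations × 60 cells
for recovery/calibration, 50 rate sets × 500 cells per condition for the
simulation ensemble, and 200–2000 cells per population for the MI checks —
sizes chosen so each statistical check is decisively powered on a single
CPU. Sample standard deviations use ddof = 1 (small populations). k-means
ties in cluster labelling break toward the earliest day. All generators and
simulations are deterministic given their seed; the SSA uses numba's
per-thread RNG seeded per cell.

## Known limitations

* The entropy estimator's plug-in bias is not subtracted; h values are
  comparable across equal-sized populations, not absolute.
* The change-model Wald intervals under-cover mildly (≈ 0.92 at nominal
  0.95) because CV sampling error grows with the CV level; the
  classification decisions at α = 0.05 are calibrated (type-I ≈ 0.05).
* Noise transfer through repressive coupling depends strongly on the
  target's kinetic regime; the default repressed target is one
  representative choice, not a universal prediction.
* The bias-measurement pathway (beta-binomial sampling of b̂) attenuates
  ξ_b estimates when the measured rather than true bias is used as the
  regressor; recovery guarantees are stated for the true-bias regressor.
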