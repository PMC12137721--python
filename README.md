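# allelenoise

Gene-expression variability under monoallelic expression, for single-cell
transcriptomics with allele-specific read counts.

Genomic imprinting and other forms of monoallelic expression leave a gene
transcribed from a single allele. With one stochastic transcription unit
instead of two, cell-to-cell variability should rise even when total
expression is dosage-compensated. `allelenoise` provides the full analysis
chain for testing and predicting that effect:

* **Observables** per gene and cell population (cells sharing donor,
  differentiation day and dish, or cell type and age):
  genetic noise η = σ/μ (the CV of expression across cells), genetic
  entropy h = Σₓ p(x)·ln(p(x)/q(x)) (KL divergence of the population's
  expression distribution from the gene's pooled distribution), allelic
  expression bias b = (r−a)/(r+a) aggregated over SNPs and cells
  (0 biallelic → 1 monoallelic), and Gaussian mutual information
  I = −ln(1−ρ²)/2 between gene pairs.
* **Change-ratio regression**: per gene,
  y = y₀·((ξ_b−1)·b+1)·((ξ_d−1)·d/d_max+1) for y ∈ {η, h, μ}, giving the
  noise/entropy/expression change ratio from bi- to monoallelic expression
  (ξ_b) and across differentiation (ξ_d), with Wald tests, gene
  classification, a pooled "overall" fit for thin data, an
  intrinsic/extrinsic decomposition, signed-bias (parent-of-origin) fits,
  monoallelic gene calling with Fisher's exact test, and
  dosage-compensation assessment (ξ^μ_b against 0.5 and 1).
* **Telegraph-model simulator** (exact Gillespie SSA, numba-compiled):
  two-state allele switching, transcription, translation, decay; dosage-
  compensated monoallelic configurations (one allele, doubled k_m — equal
  deterministic mean by construction); permissive/repressive regulatory
  links that transfer the imprinted gene's noise to target genes; rate
  ensembles spanning bursty to near-constitutive regimes.
* **MI networks**: per-stage MI matrices, per-gene MI change between
  developmental stages, high-change gene extraction (2× median rule) and
  degree-filtered network construction.
* **Synthetic data generators** with exact ground truth for both study
  designs (iPSC-like differentiation, brain-like cell-type × age), so every
  estimator is testable without external data.
* **QC**: CPM normalisation, the 0.2-CPM expression filter, the
  5-cell/25-read bias filter, and PCA/k-means matching of cells to their
  annotated differentiation day.

## Worked example

Fit the change model on a synthetic cohort whose noise truly rises 40%
from bi- to monoallelic expression and 20% over differentiation
(`examples/02_change_model.py`):

```text
    gene     xi_b     xi_d      p_b  class_b
gene0000 1.441847 1.218170 0.000128 increase
gene0001 1.244018 1.179771 0.000962 increase
gene0002 1.320876 1.104573 0.001333 increase

increase: 79 genes, decrease: 0 (true ratio 1.4 for all 80 genes)
overall: xi_b = 1.342 (true 1.40), xi_d = 1.174 (true 1.20)
```

Each row is one gene's fitted ratios: `xi_b` ≈ 1.4 means its noise at
fully monoallelic expression is ~1.4× its biallelic noise; `p_b` tests
ξ_b = 1; 79/80 genes are correctly classified as increases at α = 0.05.

Predict the amplification from the stochastic model
(`examples/03_telegraph_simulation.py`):

```text
ODE protein mean, biallelic:      40.0
ODE protein mean, mono+doubled:   40.0

mean noise change CV(mono)/CV(bi) over 10 rate sets x 300 cells:
  imprinted  1.329
  expressed  1.230
  repressed  1.181
```

Dosage compensation keeps the mean fixed, yet protein noise rises ~33% for
the monoallelic gene and is partly transferred to the genes it activates
or represses.

The other scripts in `examples/` cover the observables and QC
(`01_observables.py`), MI-network rewiring between developmental stages
(`04_mi_network.py`), and the end-to-end pipeline (`05_pipeline.py`,
equivalently `allelenoise run-all --seed 3 --outdir out/`).

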