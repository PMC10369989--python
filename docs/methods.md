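# Methods

## Per-site diversity and site classification

A codon alignment (in-frame, first column = first base of the start
codon) is summarized column by column. Characters counted for depth,
consensus and diversity are the four unambiguous bases; gaps and N are
excluded, and IUPAC ambiguity codes are mapped to N on input. Columns
with strictly more than 70% gaps are dropped. The consensus base is the
most frequent counted base provided it reaches 60% of counted characters
(inclusive); ties leave the consensus undefined. Degeneracy of a codon
position is the number of bases that, holding the other two consensus
bases fixed, encode the consensus amino acid under the bacterial genetic
code (NCBI table 11, configurable); it is undefined whenever the codon's
consensus is incomplete or the codon is a stop. Per-site diversity is
π = (N² − Σf²)/(N(N−1)), the unordered mismatch probability; sites with
depth below `min_depth` (default 4, our choice — very shallow columns
give noisy π with as few as one or two informative pairs) are logged and
carry no π.

Two consequences worth knowing:

- *Consensus censoring.* A strongly split site (minor allele above 40%)
  has no consensus, hence no degeneracy call, and drops out of the
  silent-site set. Under the neutral 1/k frequency spectrum this removes
  a π-proportional slice of polymorphism, shrinking d_min and d_max by
  the same factor; ratios (effect size) and the decay rate (effect
  length) are unaffected in expectation. The unit tests verify the
  retained-site mean against the closed form for this censoring.
- *Coordinates.* The offset l of a site defaults to its 0-based index
  among retained alignment columns ("nucleotide" mode). A "silent" mode
  indexing only 4-fold sites is available; whether distance from the TIS
  is best counted in all nucleotides or silent sites only is genuinely
  ambiguous, and the default follows the alignment-level workflow in
  which consensus and degeneracy are defined.

## Profile aggregation and the asymptotic regression

Mean diversity π̄(l) is the average of π over genes contributing a
retained 4-fold site at offset l ≤ 500 (the window over which the effect
size is defined; configurable), with weight w(l) = number of contributing
genes. Positions with fewer than `min_genes` (default 20) contributors
are dropped — at thousands of genes the weighting needs no floor, but small panels
produce unstable tail means without one.

The model π̄(l) = d_max + (d_min − d_max) e^{−cl} is fitted by weighted
least squares in the parameterization (d_min, d_max, K = ln c), which
keeps c positive, using Levenberg–Marquardt with an analytic Jacobian
(relative tolerance 1e-10, generous iteration cap). Self-start values:
d_max⁰ = mean of the last quartile of positions; d_min⁰ = π̄ at the
smallest l floored at 1e-6; c⁰ from the slope of log(d_max⁰ − π̄) against
l where positive, with a range-based fallback. The covariance is
(JᵀWJ)⁻¹σ̂² with σ̂² the weighted residual mean square. Failures
(singular Jacobian, iteration cap) return `converged=False` with
diagnostics rather than raising: a flat profile has no identifiable c and
that is a result, not an error.

Derived quantities: S_e = log₂(d_max/d_min), L_e = ln2/c, saturation
point 4·L_e. At l = L_e the curve sits exactly at (d_min + d_max)/2 — an
algebraic identity asserted to 1e-12 for every converged fit. Standard
errors by the first-order delta method:

σ_Le = ln2 · σ_K · e^{−K},
σ_Se = (1/ln2) · sqrt(σ²_dmax/d²_max + σ²_dmin/d²_min − 2 cov(d_max,d_min)/(d_max d_min)).

A second-order correction factor (1 − σ²_K/4) on σ_Le is available via
`higher_order=True`; the first-order form is the default and is the one
validated against a parametric bootstrap (500 refits), which agrees
within 25%.

A model-free effect size — log₂ of the maximum mean diversity over the
first 500 sites relative to the first position — and the Spearman
correlation ρ_l between gene length and per-gene mean silent diversity
complete the per-species summaries. Note that ρ_l under a flat
(no-gradient) model is near but not exactly zero: per-gene means over few
sites are right-skewed, which biases rank concordance slightly upward;
the tests bound this at |ρ| < 0.05 versus ~0.3 under the TIS-effect
model at default settings.

## TIS structure z-profiles

Given a gene × position matrix of unpaired probabilities over −100..+200
(probabilities are an upstream input; this package does no RNA folding),
the default estimator averages probabilities across genes per position
and z-normalizes the mean profile by the mean and SD over the 80 flank
positions (−90..−51 and +151..+190), where no TIS-specific signal is
expected. If the flank SD is zero the z-profile is defined as identically
zero. A per-gene-normalize-then-average variant is available
(`per_gene=True`); the aggregate variant is the default because the
flank statistics of the mean profile are the better-conditioned quantity
for small gene sets, and the two differ only by weighting. L_ss is the
first position ≥ +5 with z ≤ 0 (region end +200 if none), S_ss the
maximum z over +5..+200.

## Comparative layer

Covariates are Box-Cox transformed where skewed (the (x^λ−1)/λ form,
affinely equivalent to plain log/sqrt, so ranks and regression fits agree
with either convention). Extreme recombination-to-mutation ratios
(outside 1e-3..1e3 by default) are excluded. Collinearity is screened by
VIF = 1/(1−R²); regressions are run on variables centered and scaled to
unit SD so coefficients are comparable.

PGLS uses the Brownian covariance C from the tree (C_ij = shared
root-to-MRCA branch length) with off-diagonals multiplied by Pagel's λ.
For fixed λ, β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky, with σ² profiled out; λ
is estimated by bounded scalar maximization of the log-likelihood over
[0, 1] (ML by default, REML available) with explicit endpoint checks, and
its 95% CI from the profile likelihood at the χ²(1) cutoff, clipped to
[0, 1]. The bound to [0, 1] follows the interpretation of λ = 0 as
independence and λ = 1 as Brownian motion; values outside that range have
no such reading. At λ = 0, or on a star tree, PGLS reproduces scaled OLS
exactly.

Predictor selection: backward elimination scored by repeated k-fold CV
(default k = 10, 100 repetitions). Within each repetition every row is
predicted by the fold holding it out and the metrics (RMSE, R², MAE) pool
all held-out errors, so k = n is exact leave-one-out; repetitions differ
only in fold assignment and are averaged. At each step the predictor
whose removal minimizes mean CV RMSE is dropped; the ladder reports one
row per model size and the RMSE-minimal row is the selected model. RMSE
is the selection criterion; R² and MAE are reported alongside. Runs are
bit-reproducible under a seed.

## Synthetic data

The generators produce every input with known ground truth:

- *Site alleles.* Sites are monomorphic or biallelic; polymorphic sites
  draw a derived count k ∝ 1/k (the neutral frequency spectrum). Since
  E[π | polymorphic] = 1/H(n−1) exactly, making a site polymorphic with
  probability q = π_target·H(n−1) calibrates the unconditional mean to
  π_target. Triallelic sites are negligible at the diversity levels
  studied and are not simulated.
- *Codon alignments.* Codons come from 4-fold families (default 60% of
  codons; the rest from 2-fold families with fixed third base); third
  positions of 4-fold codons carry alleles targeted at
  d_max + (d_min−d_max)e^{−cl}. First/second positions are monomorphic —
  amino-acid-level variation is out of scope. Gaps are injected
  independently per cell, enough to exercise the gap filter and depth
  bookkeeping without indel realism. Gene lengths are
  min + (max−min)·Beta(1, shape) codons (shape 1 = uniform, default
  50–400 codons — a typical bacterial CDS length range).
- *Profiles at scale.* `simulate_profile` draws per-site π values
  directly from the same allele model, vectorized, so recovery
  experiments at 3000 genes × 96 strains × 200 species are feasible; the
  alignment-level path is validated end-to-end at smaller scale and the
  two share the identical allele distribution (tested).
- *Trees and traits.* Pure-birth trees (exponential waiting times,
  uniform lineage choice) scaled to unit depth; predictors iid standard
  normal; response Xβ + MVN(0, σ²V(λ_true)).
- *Unpaired probabilities.* Baseline 0.5 plus an exponentially decaying
  downstream bump plus iid Gaussian noise, clamped to [0, 1]. The bump
  amplitude is expressed in flank-SD units of the cross-gene mean so the
  generated z-profile peaks near `effect_size`. With iid positional
  noise, the first z ≤ 0 crossing is an extreme-value statistic and
  occasionally lands well before the decay length; the tests therefore
  check the replicate median.

What the generators do not emulate: linkage between sites, demography,
selection, indel evolution, RNA thermodynamics, and correlated noise
along the sequence. Passing recovery tests therefore demonstrates the
estimators are correct and calibrated for independent-site data of
realistic size, not that real alignments satisfy those assumptions.

## Problem sizes and numerical choices

The test suite runs recovery at 200 synthetic species (96 strains, 3000
genes each, profile scale) for the effect-length criterion, 500-refit
parametric bootstraps for the SE check, 200 replicates of 100-tip trees
for λ recovery, and 20 seeded runs of the CV ladder at n = 150 — sizes
chosen so the full suite completes in well under a minute of numerics
while keeping Monte-Carlo error far below the tolerances tested. The
acceptance script uses one 800-gene alignment-level species (the
alignment path is the slow one) plus 100 profile-scale species.

Degenerate inputs are reported, not raised: flat profiles
(non-convergence or S_e ≈ 0), zero flank SD (z ≡ 0), constant CV training
folds (skipped and logged). Ties: consensus ties are undefined; Spearman
uses average ranks; the greedy de-duplication pass keeps the first genome
in input order, so retained sets are order-dependent maximal (not
maximum) sets — the pairwise-threshold guarantee is what is asserted.
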