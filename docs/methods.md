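# Methods

## Model

`hybridgp` fits, by Gibbs sampling, the multi-trait mixed model

Y = Z_E β_E + Z_M g_M + Z_F g_F + Z_H h + u_M + u_F + u_H + X_AC β_AC + ε

for an n × n_T response matrix of hybrid BLUEs (one row per hybrid ×
year, one column per trait). Each random term is matrix-variate normal
with a known row covariance (a kernel) and an unknown trait covariance:

| term | row covariance | trait covariance |
|------|----------------|------------------|
| β_E (year)            | I over years (expanded Z_E Z_E′)          | σ²_E · I (isotropic) |
| g_M, g_F (GCA)        | G_M, G_F = WW′/p on parental markers      | Σ_M, Σ_F |
| h (SCA)               | H = (Z_M G_M Z_M′) ⊙ (Z_F G_F Z_F′)       | Σ_H |
| u_M, u_F, u_H (×year) | V = (Z G Z′) ⊙ (Z_E Z_E′)                 | Σ_ME, Σ_MF, Σ_MH |
| ε                     | I_n                                        | R |

The SCA kernel is the symmetric Hadamard product of the two expanded
parental kernels (PSD by the Schur product theorem). Every kernel enters
the sampler at the observation level; effects are drawn row-wise in the
kernel's eigenbasis, where the rows are conditionally independent
n_T-variate Gaussians. Each distinct kernel is eigendecomposed once per
dataset (eigenvalues truncated at 1e-10 of the maximum) and the
decomposition is reused across CV folds and strategies, since masking
changes only the response.

Conjugate full conditionals are used throughout: inverse-Wishart for each
Σ and for R, a scaled inverse chi-square for σ²_E, Gaussians for the
covariate coefficient matrix β_AC, and data augmentation (the conditional
normal of the current fit, row-wise given any observed cells) for
unobserved response cells. The update order is fixed — β_AC, each random
effect in declaration order, each trait covariance, R, augmented cells —
so a seed reproduces the draw sequence bit for bit.

Intercepts: the model has no grand mean, and BLUE responses are not
centred, so each trait is centred on its observed cells before sampling
and the means are restored at prediction time.

## Priors

The study that motivated this model reports no prior settings, so the
package uses explicit weakly-informative defaults: each trait covariance
gets inverse-Wishart(df = n_T + 2, S₀) with S₀ diagonal, chosen so every
model term (and the residual) has prior expectation equal to an equal
share of the observed per-trait phenotypic variance; σ²_E gets the
analogous scaled inverse chi-square with df 5; β_AC rows get independent
N(0, 10⁴) priors (covariate columns are standardised first, so this is
effectively flat). Any component can instead be frozen at a fixed value
(`fixed_cov` / `fixed_residual`), which is how the closed-form GBLUP
oracle comparisons in the tests are run. Default chain settings are
10,000 iterations, 5,000 burn-in, thinning 5; the tests and the
acceptance script use shorter chains (300–4,000 iterations) sized so the
full suite completes in minutes on one CPU — Monte-Carlo standard errors
are reported so the precision of any summary is visible.

## Marker processing

SNP dosages (0/1/2) pass through: (1) a missingness filter retaining
SNPs with missing fraction strictly below 0.15; (2) naive imputation —
each missing call replaced by the column mean of observed dosages, i.e.
twice the observed allele frequency, left continuous; (3) a MAF filter
removing SNPs with minor allele frequency below 0.05; (4) centring and
scaling to unit *population* SD (divisor n), which makes
mean(diag(G)) = 1 exactly for G = WW′/p. Monomorphic columns are dropped
with a logged count rather than raising. All thresholds are arguments.

## Kernels

Six parental kernels share a mean diagonal of 1 so that variance priors
are comparable across them:

* **linear** — G = WW′/p (GBLUP).
* **GK** — exp(−γ d²ᵢⱼ / mean(d²)) with d² the squared Euclidean distance
  between marker rows and mean(d²) its off-diagonal mean. The study
  reports no bandwidth; γ = 1 on this scaled axis is the package default
  (the common genomic-prediction convention) and is configurable.
* **AC_1..AC_4** — the arc-cosine kernel of an infinitely wide neural
  network with 1–4 hidden layers: base layer
  k(x,y) = (1/π)‖x‖ⁿ‖y‖ⁿ J_n(θ), θ = arccos(x·y/‖x‖‖y‖),
  J₁(θ) = sin θ + (π−θ) cos θ; deeper layers apply
  k⁽ˡ⁺¹⁾(x,y) = (1/π)[k⁽ˡ⁾(x,x)k⁽ˡ⁾(y,y)]^{n/2} J_n(θ⁽ˡ⁾) on the
  normalised layer-l kernel. Degree n defaults to 1 (ramp activation).
  The final matrix is rescaled by its mean diagonal. Cosines are clamped
  to [−1, 1] before arccos.

The kernel choice applies to G_M and G_F and therefore propagates into
H and the interaction kernels; the breeding-value model of the BV
strategy always uses the linear genomic relationship matrix over all
parents, as that model is defined on G. `ensure_psd` adds escalating
diagonal jitter (starting at the eigenvalue deficit) when numerical
asymmetry pushes a kernel's minimum eigenvalue below −1e-8.

## Parental covariates

Per trait t: X_a = (P_M,t + P_F,t)/2 and X_d = |P_M,t − P_F,t|/2, using
across-year parent means (Pmean) or posterior-mean breeding values from
the single-trait parent model (BV). Both are symmetric under exchanging
the parents. All traits' covariates enter the model for every response
trait (a full 2·n_T × n_T coefficient matrix): the covariates of
correlated traits carry information about the trait being predicted.
Covariate columns are standardised before entering the model (traits mix
days and t/ha, so this keeps the β_AC prior unit-free); constant columns
are dropped with a warning. Parents are treated as always-phenotyped:
hybrid CV masks hybrids, never parents, so the breeding-value fit sees
identical data in every fold and is computed once per dataset rather than
refit per fold — the only per-fold difference a refit could introduce is
Monte-Carlo noise.

## Cross-validation and metrics

"Untested lines in tested years": hybrids are partitioned uniformly at
random into k = 7 near-equal folds; all records of a test hybrid are
masked in every year and predicted by data augmentation. A programmatic
assertion inside the grid runner verifies on every fold that no
test-hybrid response is visible to the training fit.

NRMSE is RMSE normalised by the mean of the observed test values (the
normaliser is not specified in the motivating study; mean-normalisation
is the standard choice in this literature, and SD- and range-normalisers
are available via a flag). NRMSE is computed per trait within each year
over a fold's test observations, averaged over folds; "Global" is the
unweighted mean of the per-year values. The relative efficiency of
method x against a reference is NRMSE_x/NRMSE_ref, with the companion
percentage gain (NRMSE_ref/NRMSE_x − 1) × 100. Predictive-ability
summaries correlate predictions with observed values (or with true
genetic values on synthetic data) within year, then average across
years, so year-mean shifts do not inflate the correlation.

## Synthetic-data generator

The generator draws from exactly the model above. Defaults define the
standard desk-scale scenario: 12 males × 120 females, 3 crosses per
female (360 hybrids), 500 markers with allele frequencies uniform on
[0.1, 0.5] and 2% missing calls, 3 years with 30% of each year's hybrid
set carried into the next (so consecutive years share hybrids and every
hybrid is tested at least once — the incomplete, partially overlapping
structure of a real hybrid programme). Traits are GY (mean 6 t/ha,
SD 0.6), DTF (80 d, SD 4) and DTH (75 d, SD 4) with genetic correlations
0.40 (GY–DTF), 0.40 (GY–DTH) and 0.85 (DTF–DTH) — days-to-flowering and
days-to-heading are nearly the same developmental trait, hence the high
value. Per-trait variance shares are GCA 0.25 + 0.25, SCA 0.10
(within-year broad-sense heritability 0.60), interactions 0.05 each,
residual 0.25; year effects have SD 1 in trait units across all traits
(matching the model's isotropic year term). Parent phenotypes are the
parent's own GCA value plus noise calibrated so across-year parent means
have heritability ≈ 0.7 — informative but imperfect, which is what makes
Pmean and BV distinguishable.

The optional parental-signal scenario adds X_AC β_AC to the hybrid
responses with own-trait coefficients 0.5 on X_a and 2.0 on X_d. The
dominance-heavy weighting is deliberate: the mid-parent covariate is
largely recoverable from the GCA kernels, so a signal that a
covariate-free model cannot reach must enter mainly through
|P_M − P_F|/2.

What the generator does **not** emulate: linkage disequilibrium,
meiosis/recombination (hybrid dosages are exact parental means, as for
F1s of inbreds), selection across cycles, trial-design structure below
the BLUE level, and non-Gaussian residuals. Passing tests therefore show
that the pipeline is correct *under its own model assumptions*, not that
the model is adequate for any particular field dataset.

## Recovery benchmarks: what is attainable at desk scale

Genetic-correlation recovery is assessed against what the data can
identify. With 120 female levels, the posterior correlation from Σ̂_F
recovers the *configured* generator correlations within ±0.15. With only
12 male levels, the realized correlation of the 12 drawn male effects has
sampling SD ≈ 0.2 around the configured parameter (Fisher z = 1/√9), so
no estimator can reliably reach the configured value; Σ̂_M is therefore
compared to the realized, G_M-whitened correlation of the simulated male
effects, which the generator records. Predictive-ability benchmarks use
the correlation between CV predictions and true total genetic value
(GCA + SCA + interaction effects) within year.

## Numerical choices and edge cases

* Kernel eigendecompositions truncate eigenvalues below 1e-10 of the
  maximum; effects in the discarded subspace are identically zero.
* Inverse-Wishart draws use `scipy.stats.invwishart` driven by the run's
  single `numpy` Generator; every retained Σ and R draw is symmetric
  positive definite by construction.
* A response row with no observed cells is augmented from the
  unconditional row normal; a trait with no observed cells at all
  (prior-only run) is centred at 0 with a unit variance budget.
* Degenerate marker panels raise explicit errors (all columns filtered,
  a column with no observed calls); monomorphic and constant-covariate
  columns are dropped with logged warnings.
* `make_cv_folds` assigns hybrids, not observations, to folds; fold
  sizes differ by at most one.
* The master seed expands into per-stage seeds via
  `numpy.random.SeedSequence([master, counter])`, all below 2³¹.

## Run configuration

A YAML/JSON document with blocks `sim` *or* `inputs`, plus `strategies`,
`kernels`, `cv`, `mcmc`, `out_dir`, `seed` (see `CONFIG_SCHEMA` in
`hybridgp.config` and `examples/run.yaml`). Validation happens before
any compute and names the offending field; the CLI exits with status 2
on a schema violation. Each run writes a `manifest.json` with stage
seeds, settings and artifact hashes.

## Known limitations

* Chain-length, prior and thinning choices of the original BGLR-based
  analysis are unreported, so exact numerical agreement with published
  NRMSE tables is out of reach even with the original data; the package
  targets the *method*, with its own documented defaults.
* No REML/frequentist path and no multi-chain convergence diagnostics
  beyond Monte-Carlo standard errors.
* No kernel hyperparameter optimisation (γ is fixed unless the user
  changes it); no low-rank approximations, so fits scale as O(n³) in the
  observation count for the eigendecompositions.
* VCF/PLINK input is out of scope; convert to the dosage CSV layout with
  e.g. `bcftools +dosage` or PLINK `--recode A` and transpose as needed.
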