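# Methods

## Model

For a binary trait the engine fits the logistic mixed model under the
null hypothesis of no tested genetic effect:

    logit(μᵢ) = Xᵢα + bᵢ,     b ~ N(0, τψ)

with `μᵢ = P(Yᵢ = 1 | Xᵢ, bᵢ)`, fixed effects `α`, and a polygenic random
effect whose covariance is the genetic relationship matrix
`ψ = (1/M) A Aᵀ` of the standardized genotypes. We deliberately fit no
additional residual on the logit scale: a latent logit-scale error has no
standard meaning in a Bernoulli GLMM (its variance is not identified),
so the binary model's only variance parameter is τ. Quantitative traits
use the gaussian analogue `Y = Xα + b + ε`, `ε ~ N(0, φI)`, with both φ
and τ estimated.

Genotype standardization: column j of `A` is `(g − 2pⱼ)/√(2pⱼ(1−pⱼ))`
with `pⱼ` the allele1 frequency among non-missing calls and missing calls
imputed to the mean `2pⱼ` (zero after centering). The Hardy–Weinberg
scaling makes ψ a correlation-like kinship estimator with diagonal ≈ 1.
Monomorphic and all-missing columns are dropped with a logged count; a
column reaching standardization with p ∈ {0, 1} is an internal error, not
a user error. The bim A1 allele is the counted/effect allele everywhere —
the sign of every reported effect depends on this convention.

## Matrix-free solves

Every solve of `Σx = b`, `Σ = W⁻¹ + τψ`, uses conjugate gradients with a
Jacobi preconditioner `diag(Σ)ᵢ = 1/Wᵢ + τψᵢᵢ`; ψ enters only through
`ψv = A(Aᵀv)/M`, so the GRM is never formed for solver work. Defaults:
relative-residual tolerance 1e-5, iteration cap 5,000. A diagonal system
(τ = 0) converges in one iteration exactly. Multiple right-hand sides
(the covariate columns plus the working response) share matvecs in a
blocked CG with per-column step sizes; budget exhaustion is reported in
the returned `PCGReport`, never silently.

The column-partitioned product `Σᵢ A[:,sᵢ:eᵢ](A[:,sᵢ:eᵢ]ᵀv)/M` mirrors a
distributed layout where each worker owns a column range. Reduction order
is fixed (ascending range index) so runs are reproducible; results agree
with the unpartitioned product to ~1e-8 relative — the tolerance
acknowledges float reassociation across partitions, nothing more.
Standardized genotypes may be stored in float32 (4 bytes/entry, the
assumption behind the capacity planner `ceil(4MN/(mem_gb·10⁹))`, decimal
gigabytes); products still accumulate in float64. The default is float64.

## Fitting algorithm

Initialization: α from the fixed-effects-only GLM (IRLS), τ₀ = 0.1,
b̂₀ = 0; for gaussian traits φ₀ is the OLS residual variance. Each outer
iteration then alternates:

1. **PQL working model** (binary): with `W = μ(1−μ)` floored at 1e-10 (to
   survive quasi-separation, with a warning) and working response
   `ỹ = η + (Y−μ)/W`, solve the mixed-model system via PCG for
   `α = (XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹ỹ` and `b̂ = τψΣ⁻¹(ỹ − Xα)`, update `η, μ`, and
   repeat until α stabilizes (≤ 20 inner iterations). Gaussian traits
   need a single pass (identity link).
2. **AI-REML step**: one average-information Newton update of τ,
   `score = ½(ỹᵀPψPỹ − tr(Pψ))`, `AI = ½ỹᵀPψPψPỹ`, with
   `P = Σ⁻¹ − Σ⁻¹X(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹` applied through PCG solves, τ clamped
   to [0, ∞); a nonpositive AI falls back to bounded bisection on the
   score's sign. For gaussian traits (φ, τ) are updated jointly by a 2×2
   AI step with step-halving on the restricted likelihood.

`tr(Pψ)` is computed exactly through the dense ψ (built once and cached)
when N ≤ `exact_trace_n` (default 2,000), else by a Hutchinson estimator
with 30 seeded Rademacher probes — each probe shares one projection
solve between tr(P) and tr(Pψ). In the gaussian desk-scale path the
cached eigendecomposition of ψ makes all trace and projection terms
closed-form in the eigenbasis, while α/b̂ solves still exercise the PCG
path; this is an algebraic shortcut, not an approximation, and it is what
keeps 40 replicate N = 2,000 fits in the test suite affordable.

Outer convergence: `max(|Δα|, |Δτ|)/(|value|+ε) < tol` (default 1e-4,
≤ 30 outer iterations); non-convergence raises an error carrying the last
iterate. After convergence a short polish pass re-solves (α, b̂) at the
final τ with tightened PCG tolerance so the intercept score equation
`Σᵢ(Yᵢ−μ̂ᵢ) ≈ 0` holds to ~1e-6·N.

### Variance ratio

Step 2 uses the cheap no-GRM variance `g̃ᵀWg̃`; the ratio
`r = mean(g̃ᵀPg̃ / g̃ᵀWg̃)` over a random marker subset calibrates it to
the full-GRM variance. Defaults: 30 markers drawn uniformly without
replacement among markers with minor-allele count ≥ 20, seeded; fewer
eligible markers are used in full with a warning. With τ = 0 each ratio
is identically 1 (the projection annihilates the weighted covariate
space), which the tests exploit as an exact identity. A single global
ratio is used; MAC-stratified ratios are out of scope and noted as a
simplification.

## Association testing

For dosage or hard-call vector g (missing hard calls mean-imputed):
`g̃ = g − X(XᵀWX)⁻¹XᵀWg`, `T = g̃ᵀ(Y−μ̂)`, `var = r·g̃ᵀWg̃`,
`β̂ = T/var`, `SE = 1/√var`, two-sided normal p from `T/√var`. Variants
whose residualized variance is ≲ machine precision are flagged
untestable and written with NA p-values (tested + dropped always equals
the input count). Dosages are residualized with the same W and X as hard
calls; the variance ratio is the only relatedness adjustment.

**Saddlepoint correction.** When `|T|/√var > 2` (the conventional
trigger; configurable) and the trait is binary, the p-value is replaced
by a saddlepoint approximation to the tail of `S = Σ g̃ᵢYᵢ` with
`Yᵢ ~ Bernoulli(μ̂ᵢ)`: the CGF root `K′(ζ) = q` is found by safeguarded
Newton inside a bracketing interval; each tail uses the
Barndorff-Nielsen formula `1 − Φ(w + log(v/w)/w)` with
`w = sign(ζ)√(2(ζq − K(ζ)))`, `v = ζ√(K″(ζ))`; the two-sided p is the
sum of the two tails evaluated at `mean ± |q − mean|`, capped at 1.
Near the center (|ζ| < 1e-4) the normal p is returned as converged; a
failed root search returns the normal p flagged unconverged. Samples
with identical (g̃, μ̂) pairs are collapsed into weighted CGF terms, so
intercept-only nulls with hard calls evaluate the CGF in O(1) per
iteration rather than O(N). The uncorrected normal p is always written
alongside (`p_value_NA`) for audit.

Two properties of this approximation are worth knowing. First, for
strongly discrete scores (very few expected cases among carriers) the
exact tail is a staircase; a continuous approximation tracks its *mid-p*
version, and pointwise relative agreement with the inclusive tail is
only achievable when the expected carrier-case count is ≳ 5. The test
suite therefore checks exact-convolution agreement in that regime and
exact per-stratum calibration (by full enumeration) at MAF 0.5% under
1:99 imbalance. Second, at α as large as 0.01 the *two-sided* normal
approximation is inflated only for the rarest variants (~1.6× at MAF
0.005 under 1:99) and conservative for common ones, so aggregate
inflation over a broad MAF mix can be modest even though per-variant
calibration is poor — SPA fixes the per-variant miscalibration.

**Firth.** Optional Jeffreys-penalized logistic regression
(`ℓ + ½ log det I`) by Newton with step-halving gives finite effects and
SEs under complete separation; when enabled in Step 2 it refits only
variants with `p < 0.05` (configurable) to bound cost, replacing BETA/SE
in the output.

**Chunking and batching.** Variants are split into equal contiguous
chunks processed independently (optionally by a thread pool) and
concatenated in input order, so output files are byte-identical for any
chunk/worker combination — chunking is over variants, not samples, since
score tests decompose naturally that way. A manifest TSV
(`trait_id, null_model, variance_ratio, output`) drives multi-trait
batches against a single genotype load.

## Synthetic cohorts

The generator emulates exactly what the fitting step assumes. Genotypes:
founders are Binomial(2, pⱼ) with pⱼ ~ U(maf_range); sib pairs/quads are
built by Mendelian transmission from stored parental haplotypes (parents
are not in the sample), giving sibling GRM expectation 0.5. Phenotypes:
b is drawn exactly from N(0, τψ) using an eigenfactor of the cohort's
own dense GRM — the same ψ the fit sees, so recovery experiments are
internally consistent — then binary Y ~ Bernoulli(expit(c + Xα + b))
with the intercept c solved numerically for a target prevalence, or
quantitative Y = Xα + b + ε with unit-variance noise. Extreme
case-control imbalance (e.g. 1:99) is produced by ascertainment:
sampling exact case/control counts from a larger simulated pool. All
randomness flows from the single config seed.

What the generator does *not* emulate — linkage disequilibrium,
population stratification/admixture, genotyping error, informative
missingness — bounds what green tests mean: they validate the
estimators and corrections under the model's own assumptions, not
robustness to real-data violations of them. The exact dense-GRM draw of
b is O(N³) and intended for desk-scale N (≲ a few thousand; τ = 0
cohorts of any size skip it).

## Numerical and design choices

- Internal indices are 0-based half-open; 1-based bim positions exist
  only at the file boundary.
- Null-model serialization is a single self-describing JSON document
  (α, τ, φ, μ̂, W, residuals, b̂, X, sample ids) plus a small
  variance-ratio sidecar — sufficient to run Step 2 without refitting,
  and deliberately not interoperable with upstream GMMAT/SAIGE binary
  model files, whose format is unspecified.
- The dosage TSV dialect (chrom, pos, id, a1, a2, one column per sample,
  values in [0,2]) keeps imputed-data ingestion dependency-light; VCF and
  BGEN are out of scope.
- The capacity planner takes the ceiling of `4MN/mem_bytes` (a device
  count must cover the matrix) and clamps at 1; it follows the N-samples
  × M-variants orientation consistently.
- Test-design note: with *unrelated* samples, τ is identified only
  through the GRM's eigenvalue spread and the REML score SD scales like
  √(2M)/N, so null-recovery checks (truth τ = 0) use M well below N —
  at M ≥ N a single estimate can sit far from 0 even when it coincides
  with the exact REML optimum.
- Sizes used by the heavier test experiments: variance-component
  recovery uses 20 replicate sib-quad cohorts of N = 2,000, M = 3,000
  per τ value; calibration experiments use 10,000 null variants at
  N = 20,000 (1:99) and N = 2,000 (balanced); the acceptance script uses
  slightly smaller replicates of the same designs.

## Known limitations

- Single variance component only; no leave-one-chromosome-out scheme, no
  sparse-GRM two-stage fitting.
- PQL-based binary fitting carries the usual small-N/rare-trait bias in
  τ̂; the score test itself is calibrated through μ̂ and r rather than
  through τ̂'s absolute accuracy.
- SPA p-values for extremely discrete scores approximate the mid-p tail
  (see above); gene/region set tests, conditional analyses and GxE are
  out of scope.
- The partitioned product and planner model a distributed layout's
  algebra; actual multi-process/multi-device execution is out of scope.
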