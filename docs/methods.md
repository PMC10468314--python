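# Methods

## Model and scaling

All analyses are Gaussian linear mixed models over entries (clonally
replicable genetic units) or their within-environment means,

    y = Xb + Σ_i Z_i u_i + ε,    u_i ~ N(0, K_i σ²_i),    ε ~ N(0, R0 σ²_ε),

estimated by REML.  The average semivariance (ASV) of a random term — half
the average pairwise variance of a difference between entries — equals
`σ²_i · tr(Z_i K_i Z_iᵀ P)/(n−1)` with `P = I − J/n`.  The package scales
covariance structures so that constant is 1 wherever possible:

* additive genomic kernel `K_ASV = (n−1)·X̄X̄ᵀ/tr(X̄X̄ᵀ)` from column-centered
  dosages; trace `n−1`, element sum 0.  We adopt the trace-`n−1` convention
  (mean diagonal `(n−1)/n`, not exactly 1): it is the only scaling under
  which the polygenic ASV equals `σ²_g` exactly and the per-term variances
  add up to `(n−1)⁻¹tr(VP)`.
* dominance kernel `K_ASV·D`: same construction on `W = 1 − |X|`.  Undefined
  (degenerate-kernel error) for fully inbred data.
* factor-coded loci: `k_M = (n − n⁻¹Σ_h n_h²)/(n−1)` converts the REML
  component of a genotype-class factor to the ASV scale; embedding
  `K_M = k_M⁻¹I` as the class covariance is numerically equivalent to the
  post-hoc multiplication (verified to 1e−6 in the tests) and is what the
  higher-level fits use.

Monomorphic loci center to zero columns and are silently inert; missing
genotype calls are rejected.  Positive-semidefiniteness checks accept
eigenvalues down to −1e−8 of the largest.

## REML engine

A dense-covariance multi-kernel engine: any term may carry an arbitrary
level covariance, any component (including the residual) may be fixed, and
the residual base structure may be the identity, per-observation weights, or
a full covariance supplied as a weight matrix `W = Ω⁻¹` (the fully efficient
stage-two configuration: residual fixed at 1, structure `Ω`).

* Schedule: 2 expectation–maximization warm-up iterations, then
  average-information (AI) steps.  Each AI step is accepted only if it does
  not decrease the restricted likelihood (checked with a Cholesky-only
  evaluation when the proposed move is large; small near-convergence moves
  are accepted directly), with step-halving and an EM fallback otherwise.
  A pure-EM mode is available.  A longer EM warm-up adds robustness but, with
  the likelihood-guarded AI steps, no accuracy, so the default warm-up is
  short.
* Convergence: maximum relative component change < 1e−8, at most 200
  iterations; non-convergence is flagged on the result, not raised.
* Non-negativity: components proposed below zero are bent to
  1e−10·var(y); a component bent twice is constrained at that boundary
  ("bend-and-fix").  Unconstrained directions (e.g. the G×E/residual ridge of
  a naive stagewise fit) are handled by a ridge-damped AI solve plus the EM
  fallback; the identified sums converge even when the split is arbitrary.
* Initial values: equal split of the response variance across free
  components, net of fixed contributions; callers may pass explicit starts
  (the experiment runner warm-starts each replicate population from the
  previous one's estimates, which changes iteration counts, not optima).
* Singular kernels need no reparameterization since all computations go
  through the marginal covariance `V`, which the residual keeps positive
  definite; a kernel's retained spectral rank (relative eigenvalue cutoff
  1e−10) is used as its effective dimension in EM updates.
* Likelihood-ratio tests for extra variance components use the 50:50
  mixture of a point mass at zero and χ²(df) (boundary correction), and
  refuse to compare fits whose fixed-effect designs differ.

Computationally, an iteration costs one `n×n` Cholesky factorization and
inverse plus O(n²) trace bookkeeping per term (factor terms go through
sparse incidence aggregation, never dense `n²q` products).

## Stagewise analysis of multi-environment trials

Stage one fits each environment with entries fixed (cell-means coding, no
intercept) and blocks random, returning the adjusted entry means and their
full covariance `Σ_e`.  For complete randomized block designs the REML
solution is closed-form (balanced ANOVA; `Σ_e` compound symmetric), which is
used automatically and matches the iterative fit.  The `Σ_e` are assembled
corner-to-corner into `Ω` and inverted blockwise.

Stage two fits environment fixed effects, the marker (K_M), the polygene
(K_ASV), a residual genetic term and G×E to the stacked entry means under
one of three residual conventions: naive (free scalar identity — confounds
G×E with the residual), weighted (fixed unit residual, diagonal of `Ω⁻¹` as
weights; one of several possible diagonal approximations, chosen for
simplicity), and fully efficient (fixed unit residual, full `Ω⁻¹`).

The single-stage reference fit of the plot data uses an exact orthogonal
stratum decomposition when the design is a balanced complete clonal RCBD:
the within-cell stratum (block contrasts + plot residual) is independent of
the cell-mean stratum and carries all the information on σ²_block and
σ²_plot (pooled balanced ANOVA = REML there), while the cell-mean stratum
carries all genetic information with the residual fixed at σ̂²_plot/r — the
between stratum by itself cannot separate G×E from the cell-mean residual,
so the joint REML optimum factorizes exactly.  Unbalanced data fall back to
a generic plot-level fit; the two routes agree on balanced data (tested).

## Synthetic data

The generator emulates a structured population without external data:

* Markers: an AR(1) latent Gaussian field along the genome (default
  ρ = 0.9) thresholded per locus at the symmetric quantiles that give
  heterozygote frequency `H` (0.38 outbred, 0 inbred).  This preserves
  "correlated, structured markers" but not the block-wise LD, allele
  frequency spectrum or relatedness structure of a real panel — bias
  results transfer, precision constants need not.
* Focal locus: multinomial 1:2:1 (outbred) or 1:0:1 (inbred), non-empty
  classes guaranteed.
* Trait: additive polygene `X̄β` (iid marker effects), optional dominance
  polygene `W̄δ`, focal-locus effects, residual genetic term, optional G×E,
  block effects (variance 20 by default — a conventional choice, the
  experiments are insensitive to it) and plot residuals with plot variance
  `r·θ_ε` so the entry-mean residual variance is `θ_ε`.  Focal-locus
  effects are drawn from the fitted model's own prior — iid effects per
  genotype class, and for the additive/dominance split additionally iid
  effects per genetic state (hom/het) — so the estimators are unbiased for
  the targets.  By default every component is rescaled so its realized ASV
  equals its target exactly ("exact scaling"), making per-population truths
  sharp; expectation scaling is available.
* Default targets mirror the study conditions: θ_g = 66 (split 33/33 when a
  dominance polygene is present), marker σ²_m = 66 (θ_m = k_M·66) or
  θ_mA = θ_mD = 20 for the split, θ_gR = 50, θ_GE = 90, θ_ε = 40, with
  n ∈ {500, 1000, 1814}, m = 5000, r ∈ {1, 2, 4}.

With one observation per entry the residual-genetic and residual structures
coincide, so single-environment analyses treat the entry-mean residual
variance as known (r = 1) or estimate it from the pooled within-entry
replicate variance (r > 1) and fix it in the entry-mean fit — the
known-residual convention of stagewise analysis.

## Bias experiments and what they show

`run_bias_experiment` loops simulate → fit → ASV-scale and reports
per-quantity mean relative biases with Monte-Carlo standard errors
(non-converged replicates are excluded and counted; none occur at the
default settings).  Replication defaults to 100 populations per experiment;
the test suite runs the multi-environment experiment at 30 populations and
the design-pattern checks at 30 populations per cell, which keeps the whole
suite desk-scale at the cost of proportionally wider Monte-Carlo bands (the
assertions widen with the measured standard errors).

Measured behaviour at these scales: kernel identities hold to 1e−10;
single-locus, polygenic (additive and dominance) and all five
multi-environment components are centered within a few percent; the fully
efficient two-stage fit reproduces single-stage components to <1% per
dataset at n = 500; precision improves with entries for genetic terms and
with clonal replicates for the residual only.

**Known limitation — the single-locus additive/dominance partition.**  All
marker information lives in two class-mean contrasts: the homozygote
difference (additive only) and the heterozygote deviation (a fixed mixture
of both components).  The partition therefore rests on roughly one effective
degree of freedom per population: per-population estimates of θ_mA and θ_mD
have standard deviations near 100% of their values, sit on the zero boundary
in a large fraction of populations, and their likelihood-ratio comparison
against the unsplit model is erratic.  The estimates are mean-unbiased
across many populations — which is what the bias experiment verifies — but
no convergent constrained REML yields sharp per-population partitions, a
near-zero split-sum residual in every population, and a uniformly
non-significant likelihood ratio at the same time.  Users should read
single-population estimates of this split as indicative only; the total
marker variance θ_m is sharp.
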