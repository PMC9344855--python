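# Methods

## Problem setting

Multiplex tissue imaging (mIHC, MIBI and related platforms) yields, after
segmentation, a table of cells with a continuous intensity per marker.
Whether two or more markers *co-express* in a subject's tumor
microenvironment is conventionally decided by binarizing each marker at a
positivity cutoff and counting multi-positive cells — a step that is
subjective, platform-dependent and statistically lossy. This package
instead treats the `p` marker intensities of subject `j` as continuous
random variables on `[0, 1]` and quantifies their dependence directly.

## The co-expression statistic

For subject `j` with joint density `f_{1..p}` and marginals `f_k`, define

    V_J = ∫ f_{1..p}(x)² dx
    V_C = ∫ f_{1..p}(x) · Π_k f_k(x_k) dx
    V_M = ∫ Π_k f_k(x_k)² dx

The Euclidean quadratic mutual information is
`EQMI = V_J − 2 V_C + V_M = ∫ (f_{1..p} − Π_k f_k)²`, which is zero if and
only if the markers are independent and, unlike Pearson correlation,
responds to dependence of any shape. Because its scale depends on the
densities themselves, subjects are compared on the standardized value

    EQMI* = (V_J − 2 V_C + V_M) / (V_J + V_M)  ∈ [0, 1].

The Cauchy–Schwarz variant `CSQMI = log(V_J V_M / V_C²)` is reported for
reference but not used in testing.

### Estimation without a p-dimensional grid

Estimating the joint density and integrating numerically is infeasible
beyond a few markers. Plugging Gaussian KDEs (bandwidth `h_k` for marker
`k`) into the V integrals and integrating analytically — via the kernel
self-convolution `∫ G_h(x−a) G_h(x−b) dx = G_{√2·h}(a−b)` — collapses
every integral onto pairwise kernel sums:

    K_k(i,s) = G_{√2·h_k}(X_ki − X_ks)
    V_J = n⁻² Σ_i Σ_s Π_k K_k(i,s)
    V_C = n⁻¹ Σ_i Π_k [n⁻¹ Σ_s K_k(i,s)]
    V_M = Π_k [n⁻² Σ_i Σ_s K_k(i,s)]

This is exact (not an approximation of the plug-in integrals), holds for
unequal bandwidths, and costs O(n²·p) time and O(n²) memory — one
marker's kernel matrix at a time. Two independent oracles pin the
implementation: a literal triple-loop transcription of the sums
(agreement to 1e−12 relative) and, for p = 2, trapezoid quadrature of
the gridded KDE integrals (agreement to better than 1e−4 relative; this
also fixes the `√2·h_k` kernel-inflation reading, since any other
bandwidth convention fails the quadrature check).

### Bandwidths

Bandwidths are selected per subject from that subject's own cells:

- **Plug-in (default, p ≤ 6):** a univariate two-stage direct plug-in
  per marker (normal-scale ψ₈ seeds a kernel estimate of ψ₆, which seeds
  ψ₄, giving `h = (2√π ψ₄ n)^(−1/5)`), i.e. a diagonal multivariate
  selector. On N(0, 1) samples it is checked against the AMISE optimum
  `(4/(3n))^(1/5)σ` to within 25% (the sampling slack of the ψ
  estimates at n = 1000).
- **Silverman:** `h_k = 0.9·min(sd, IQR/1.34)·n^(−1/5)`, used
  automatically when p > 6 (the stage-wise plug-in sums become the
  bottleneck there) or when a plug-in stage produces a non-usable ψ
  estimate (warned).
- **Fixed:** a user-supplied scalar or per-marker vector, for
  sensitivity analysis.

Bandwidths are floored at 1e−6 so near-duplicate intensities cannot
overflow the kernel. Subjects with fewer than 2 cells or a constant
marker are excluded with a warning rather than failing the run.

## Association testing

With `E_j` the per-subject statistic (EQMI*, |Pearson r|, or a cluster
label) and `C_j` optional covariates:

- continuous outcome: OLS `Y = Cβ + Eγ + ε`, Wald test of the E terms
  (optionally polynomial in E, jointly tested);
- binary outcome: logistic regression, Wald test of γ; complete
  separation is flagged, not raised;
- survival outcome: Cox proportional hazards
  `λ_j(t) = λ₀(t)·exp(C_jᵀβ + E_jγ)`, 1-df likelihood-ratio test of γ,
  hazard ratio `exp(γ̂)`. Ties are handled by the Efron approximation
  (lifelines); a Breslow option is provided through an internal
  partial-likelihood maximizer and agrees with Efron on tie-free data.

The multi-marker scan enumerates every subset of ≥ 2 markers (refused
above p = 10, where 2^p explodes), computes EQMI* per subset and tests
each; Bonferroni correction is applied within each subset size, because
subsets of different sizes answer different questions — a size-m subset
is called significant at `α / (#subsets of size m)`.

## Baselines

The thresholding comparator binarizes at per-marker pooled quantiles
(Median-Thresholding q = 0.5, Threshold 1 q = 0.95, Threshold 2
q = 0.99; linear-interpolation quantiles), with strict positivity
`X > t`. Per subject and unordered marker pair the proportions of
double-positive / first-only / second-only cells form the feature vector
(all 2^p − 1 patterns available as an opt-in); subjects are grouped by
agglomerative clustering (Ward linkage, Euclidean distance — both
configurable since the convention is not canonical; labels renumbered by
first appearance for determinism) and the M = 2 cluster label is tested
as above (an (M−1)-df joint test for M > 2). The correlation comparator
uses the absolute per-subject Pearson correlation of a marker pair.

## Synthetic cohorts

Generators produce two latent groups of subjects — dependent (I = 0) and
(near-)independent (I = 1), equiprobable by default:

- **copula2:** Gaussian copula over Beta(1.5, 170) and Beta(1.6, 35)
  marginals (heavily right-skewed, mimicking real functional-marker
  intensity profiles); per-subject copula correlation U(0.75, 0.9) vs
  U(0, 0.15). Linear dependence: EQMI* and |r| are nearly one-to-one.
- **squared:** X₂ = (X₁ − 0.05)² + e, X₁ ~ U(0, 0.1),
  e ~ U(0, 0.0005): strong dependence, exactly zero population
  correlation.
- **circular:** X₂ = 0.05 + s·√(0.05² − (X₁ − 0.05)²) + e with
  s ~ U(−1, 1). The literal reading of "a random number between −1 and
  1" is uniform, which fills the disc; a Rademacher (±1) option traces
  the circle itself — the method comparisons hold under both.
- **copula3 cases A/B/C:** three Beta marginals
  ((1.5, 170), (1.6, 35), (1.6, 35)); pairwise copula correlations
  U(0.4, 0.6) vs U(0.2, 0.4), with case B pinning ρ₁₃ = 0 and case C
  additionally ρ₂₃ = 0, so the between-group contrast shrinks A → C.
  Correlation draws are rejected and redrawn if the matrix is not
  positive definite.

Outcomes are `Y_j = I_j·β + ε_j`, `ε ~ N(0, σ²)` with σ = 1; β spans
{0, 0.5, 1, 1.5, 2}, from a null to a ~2 SD group separation. The noise
is redrawn `outcome_reps` times over fixed intensities; power is the
rejection fraction at α = 0.05, averaged over `dataset_repeats`
regenerated cohorts, with the binomial Monte-Carlo standard error.

One comparative result of the power engine is worth spelling out. In
the circular scenario, thresholding at the pooled *median* carries no
signal at all: with t = 0.05 every pairwise positivity proportion is
0.25 in both groups, so its power stays at the test level. Thresholding
at extreme quantiles (q95/q99), however, is genuinely informative there
— the single-positive proportion of the second marker differs strongly
between groups (≈ 0.01 vs ≈ 0.05 at q95), and at 1000 cells per subject
that difference is many standard errors wide, so those comparators reach
the same power as EQMI*. The advantage of EQMI* in the two-marker
non-linear scenarios over the correlation statistic is unconditional;
its advantage over thresholding depends on which cutoff the comparator
happens to use, which is precisely the arbitrariness the threshold-free
statistic removes.

What these cohorts do *not* emulate: within-subject image structure,
spatial cell coordinates, cell-type mixtures, varying cell counts per
subject, or intensity artefacts (hot pixels, batch effects). Passing the
power comparisons therefore demonstrates the statistical behaviour of
the estimators under the stated dependence shapes, not robustness to
real-data preprocessing.

## Problem sizes and numerical choices

- Test-suite and reproduction-script power studies use 20 outcome
  repetitions × 5 cohort repeats at N = 40 subjects × 1000 cells — the
  package's scaled-down study configuration; the full-budget defaults
  (100 × 20) remain the `SimScenario` defaults for standalone use.
- The p = 2 quadrature check uses a ≥ 400-point-per-axis trapezoid grid
  padded 4 bandwidths beyond [0, 1] (and beyond the data range if
  wider), so the ℝ²-integrated kernel identities are reproduced rather
  than the truncated-domain integrals.
- EQMI* is clipped to [0, 1] only within 1e−10 absolute slack; a value
  outside that slack raises, since it would indicate an estimator bug
  rather than roundoff.
- Null-calibration checks draw the statistic independently of the
  outcome, isolating test calibration from estimator behaviour.
- CSQMI is reported as +inf when V_C = 0 (possible only in pathological
  inputs) rather than raising.

## Known limitations

- EQMI* measures the *amount* of dependence, not its shape: a linear and
  a circular subject can share an EQMI* value.
- The combination scan's per-size Bonferroni correction ignores the
  strong dependence among overlapping marker subsets and is
  conservative.
- Subject-level bandwidths mean EQMI* values are not invariant to
  pooling cells across subjects; per-subject estimation is intentional
  (each subject has its own densities) but makes between-study
  comparisons bandwidth-sensitive. A fixed-bandwidth override exists
  for such comparisons.
- The multinomial (> 2 class) categorical outcome is not supported;
  binary logistic only.
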