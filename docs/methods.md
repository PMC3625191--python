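# Methods

This note documents the statistical model behind `fcmvpa`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## From time series to features

The package's contract starts at regional mean BOLD time series (one
T × R matrix per subject).  Everything upstream — motion correction,
spatial normalization, smoothing, parcellation — is assumed done by a
volume-processing pipeline and is out of scope.

Per subject, the feature pipeline is **nuisance regression → band-pass
→ correlation → Fisher z**:

- *Nuisance regression* projects every region column onto the
  orthocomplement of [intercept | nuisance columns] by OLS.  Typical
  nuisance columns are six motion parameters, the global mean, and
  white-matter and CSF signals.  Rank-deficient designs are repaired by
  dropping dependent columns (warned).  The operation is idempotent and
  leaves residuals exactly orthogonal to the regressors.
- *Band-pass*: Chebyshev type I, order 5, passband 0.01–0.08 Hz,
  applied forward–backward (`sosfiltfilt`) for zero phase.  Zero-phase
  filtering matters because Pearson correlation at lag 0 is the
  connectivity measure; a phase-distorting filter would shift regions
  relative to one another.  Because the two passes square the magnitude
  response, the default passband ripple is 0.1 dB (worst-case in-band
  gain ≈ 0.97); a 0.5 dB design would already attenuate in-band
  amplitudes by more than 10%.  Type, order, ripple and band edges are
  all `RunConfig` fields.
- The regression → filter order is fixed (filtering first and then
  regressing unfiltered nuisance signals can re-introduce
  high-frequency nuisance variance).  On wide-band noise the two orders
  differ by less than sampling noise.
- *Fisher z*: features are atanh(r) of the R(R−1)/2 upper-triangle
  correlations, in row-major pair order (1,2), (1,3), …, (R−1,R).  The
  ordering is internal only — every report names features by region
  pair.  Correlations are clipped to ±(1 − 10⁻⁷) first so collinear
  regions give large-but-finite features.

## Feature scoring: Kendall tau-b

Features are scored against the ±1 labels with the tie-corrected
tau-b.  With n₁ positives and n₂ negatives, tau-b reduces to a
Mann–Whitney form, (C − D) = 2U₁ − n₁n₂, normalized by
√((n₀ − t_x)(n₀ − t_y)); the implementation scores all features in one
vectorized pass over column midranks and is pinned against an O(n²)
pair-counting oracle and against `scipy.stats.kendalltau` in the tests.

Two consequences worth knowing:

- With binary labels |τ| cannot reach 1: its ceiling is
  √(n₁n₂/n₀) ≈ 0.72 for balanced groups of 15.  Thresholds on
  "discriminative power" must be read on that scale.
- The denominator is feature-independent except for ties in the
  feature, so ranking by |τ| is essentially ranking by |C − D|.

Sign convention: +1 = control, so τ > 0 ⇔ the connection is weaker in
patients ("uncoupling").  Selection is top-N by |τ| (primary) or a
power threshold (secondary); ties break toward the smaller feature
position so repeated runs are deterministic.

## Locally linear embedding

Standard three-step LLE: Euclidean k-NN; constrained reconstruction
weights; eigenvectors of M = (I−W)ᵀ(I−W).  The constant eigenvector
(eigenvalue 0, guaranteed by row-stochastic W) is always discarded and
the next d eigenvectors form the embedding.  The package does not
require k > d: the eigenproblem is well-posed for any d ≤ n − 2, and
the standard operating point below indeed uses k = 8 with d = 10.

**Local weight solver.**  The k × k Gram matrix G of a neighborhood is
often singular (k larger than the local intrinsic dimension — the
normal situation on a manifold).  The solver eigendecomposes G and

1. solves exactly when G is well-conditioned (the weights are then
   exact minimizers of the reconstruction cost);
2. when G is singular and the constraint vector 1 has a component in
   the null space, returns that component rescaled to sum 1 — an
   *exactly* zero-cost reconstruction.  This is what makes locally flat
   data reproduce exactly (planar clouds embed with Procrustes residual
   at machine precision, a property the tests assert);
3. otherwise falls back to the usual trace-scaled ridge
   (G + reg·tr(G)·I, reg = 10⁻³).

An unconditional ridge — the common implementation shortcut — was
rejected because it perturbs the weights of exactly-reconstructable
neighborhoods and destroys the exact-recovery property by several
orders of magnitude.

**Out-of-sample extension.**  Cross-validation must embed a subject
that was not part of the manifold fit.  A held-out point is mapped by
solving the same constrained weight problem over its k nearest
*training* points and combining their embedding rows.  Refitting the
manifold with the test point included would leak it into training and
is never done.  This is the package's most consequential choice among
defensible alternatives (Nyström-style extensions, per-fold refits);
it is exact for locally flat data and standard practice elsewhere.

## Classifiers

- **SVM (primary):** scikit-learn's SVC, RBF kernel, C = 2 by default.
  The kernel width defaults to γ = 1/(d·var(X_train)) ("scale") since
  no width is part of the reference operating point; both C and γ are
  sweepable.
- **Fisher LDA:** closed form w = S_w⁻¹(μ₊ − μ₋), threshold at the
  midpoint of the projected class means (equal priors); ill-conditioned
  pooled covariances get a 10⁻⁶·tr(S_w)/d ridge.  Cross-checked against
  scikit-learn's LDA with equal priors.
- **Fuzzy C-means:** two clusters, fuzziness m = 2, membership updates
  to Δu < 10⁻⁶ or 300 iterations; deterministic initialization at the
  two training points farthest apart, so no seed sensitivity.  Clusters
  are mapped to the label holding their membership majority; if both
  map to one label the cluster with the weaker majority is forced to
  the other (warned).

## Evaluation

**LOOCV.**  Every fold re-runs feature scoring and selection and refits
the embedding on the n − 1 training subjects only; the held-out subject
is then embedded out-of-sample and classified.  A structural test
verifies that perturbing the held-out subject's features cannot change
the fold's training computations.

**Metrics.**  GR = overall correct proportion; the two per-class rates
are reported neutrally as `rate_pos` (controls) and `rate_neg`
(patients).  The names SS/SC attach to them through a convention
switch, because published usage is inconsistent: by definition
sensitivity is the patient-class rate (`ss_convention="patient"`, the
default), but some reported SS/SC pairs are only arithmetically
consistent with SS computed over the control group
(`ss_convention="printed"`).  GR is unaffected.

**Permutation test.**  Labels are shuffled n_perm times and the *full*
LOOCV — including per-fold selection — is re-run per shuffle, with
hyperparameters fixed at their real-label values.  Re-using the
real-label feature selection would inflate significance.  The p-value
is the add-one estimator (1 + #{GRₙᵤₗₗ ≥ GR₀})/(1 + n_perm), which is
never 0 and floors at 1/10001 ≈ 10⁻⁴ for 10⁴ permutations.

**Hyperparameters.**  `sweep` optimizes (n_features, k, d, C, γ) by
LOOCV on the full sample, with ties resolved toward fewer features.
This mirrors the reference analysis but is optimistically biased;
`loocv_nested` offers the unbiased nested variant (inner sweep per
outer fold) for users who want honest generalization estimates.

**Mass-univariate check.**  Per-feature two-sample t-tests
(pooled-variance Student by default, the classical neuroimaging
convention; Welch behind `equal_var=False`) with Benjamini–Hochberg
FDR at q = 0.05, as a conventional counterpart to the multivariate
signature.

## Discriminative weights

weight(connection) = mean τ over folds where selected × occurrence/n_folds.

The mean is taken over selected folds only (unselected folds record no
τ in this workflow).  Connections with occurrence ≥ `retention_min`
(default 51, i.e. ≈ 76% of 67 folds) form the stable signature.
Region weights assign |weight|/2 to each endpoint; network weights
assign |weight|/2 to each endpoint's network and |weight| to the
network pair (both halves to the same network when the connection is
within-network).  Absolute weights are used for the magnitude rollups
while the connection report preserves signed mean τ, so the
conservation identity Σ region = Σ network = Σ retained |weight| holds
exactly (asserted to 10⁻¹⁰ on random fixtures).

## Synthetic cohorts

The generator draws each subject's regional signals as a stationary
Gaussian AR(1) process z_t = φ·z_{t−1} + √(1−φ²)·ε_t with
ε_t ~ N(0, Σ_group), via the Cholesky factor of the group's target
correlation matrix.  Σ is a block structure: r_within = 0.5 inside each
of 7 networks, r_between = 0.3 across them; a planted set of
between-network pairs is reduced by Δr in the patient group.  If
planting breaks positive definiteness, the target is repaired by
eigenvalue clipping at 10⁻⁶ plus diagonal renormalization and the
Frobenius distortion is logged.

Defaults mirror a typical clinical study scale: 35 controls + 32
patients, R = 116, T = 145 usable volumes at TR = 2 s, φ = 0.3, 20
planted connections at Δr = 0.3, no extra observation noise
(`noise_sd = 0`; Σ already carries unit-variance noise structure).

**What this emulates and what it does not.**  The pipeline consumes
only second-order structure, and the generator controls exactly that:
target correlations, temporal autocorrelation, group differences.  It
does *not* model hemodynamic convolution, head motion, scanner drift,
physiological cycles, or between-subject variability beyond sampling
noise of the correlation estimates.  Passing tests therefore establish
that the implementation recovers known second-order ground truth — not
that the method is robust to the artifact structure of real fMRI.

## Problem sizes used by the test suite and acceptance run

- Planted-recovery run: the default cohort above, operating point
  top-22 features, k = 8, d = 10, C = 2, retention ≥ 51/67.
- Null chance-level check: 10 balanced null cohorts of 100 + 100
  subjects, R = 20 (large groups keep the standard error of the
  10-seed mean, and the small pessimistic bias LOOCV acquires through
  per-fold selection, well inside the ±3-point band).
- Permutation-test calibration: 200 null cohorts of 15 + 15 subjects,
  R = 20, 99 permutations each, reduced operating point (top-10
  features, k = 8, d = 3); rejection rate at α = 0.05 compared against
  10%.  The add-one estimator is conservative, so the expected rate is
  slightly below 5%.
- The acceptance script re-runs the default-cohort pipeline, a
  99-permutation significance test, and 5 reduced-scale null cohorts.

## Known limitations

- Binary classification only; no multi-class or regression targets.
- LOOCV only (plus the nested variant); no k-fold alternatives.
- The LLE eigenproblem assumes the k-NN graph is connected; severely
  fragmented graphs produce near-degenerate bottom eigenvectors.
- Whole-sample hyperparameter optimization by LOOCV is optimistically
  biased by construction; use the nested mode when the generalization
  estimate itself is the quantity of interest.
- The NIfTI reader is a convenience (within-label voxel averaging); it
  performs no volume preprocessing.
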