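# Methods

## Model and procedure

The package analyses two blocks of subject-level data, X (behavioural /
demographic measures) and Y (connectivity edges), observed on the same N
subjects.  The working model is latent-factor: each functionally defined
sub-domain of a block carries a small number of latent factors plus
independent noise, and a few latent *modes* are shared between blocks,
inducing cross-block correlation.  The analysis pipeline estimates, in
order:

1. **Preprocessing.**  Quality control removes variables with >50% missing
   entries, zero standard deviation, or a modal value covering >95% of
   non-missing entries (reasons reported in that order, evaluated on the
   pre-imputation values).  Remaining missing entries are imputed by the
   column median — a rank-stable choice, since the next step only uses
   ranks.  Each column is then mapped to Blom scores,
   Φ⁻¹((r − 3/8)/(N + 1/4)) with average ranks for ties, giving
   approximately standard-normal marginals robust to outliers.
   De-confounding replaces each column by its OLS residual on an intercept
   plus the confound columns (z-scored for conditioning; residuals are
   unaffected).  Squared, re-centered confound copies can be appended via
   configuration — no automatic selection.  Finally, sign-flipping negates
   every variable whose pairwise-complete correlation with a benchmark
   variable is strictly negative, then applies manual overrides; this
   aligns variable polarity ("larger = better") without changing any
   covariance eigenvalue, dimension estimate or canonical correlation
   (orthogonal-sign invariance, verified by property tests).

2. **Per-sub-domain dimension selection (two-way CV PRESS).**  Subjects are
   split into folds.  On each fold, the held-in rows are decomposed by SVD
   and each held-out *column* j is predicted at candidate dimension k from
   the other held-out columns through the held-in loadings with row j
   removed, via the Moore–Penrose pseudo-inverse.  Squared prediction
   errors are accumulated over columns and folds; the chosen dimension is
   the smallest k at the minimum.  PRESS is defined with squared norms
   throughout, so it is a sum of squared errors (the interior-minimum
   property and the monotone naive curve are both asserted in tests).  The
   candidate range is k = 1..min(P−1, N_held-in−1): the leave-one-column
   prediction is undefined at k = P, and the SVD rank caps at the held-in
   row count.  The CV is repeated (default 50 times; repeat i uses seed
   `seed + i`) and the modal dimension is taken, ties resolving to the
   smallest (parsimony).  Single-variable sub-domains bypass CV with k = 1.
   Blocks enter the CV as produced by preprocessing (inverse-normal
   transformed, hence near mean-zero); per-fold re-centering is available
   as an option (`center_folds`).

3. **Rotation and concatenation.**  The chosen loadings are varimax rotated
   (Kaiser row-normalization on, convergence tolerance 1e-6 on the
   criterion, at most 1000 iterations, column signs fixed so each column's
   largest-magnitude entry is positive).  Rotation is orthogonal, so all
   CCA outputs are invariant; only the factor-level interpretation changes.
   Rotated components from all sub-domains are concatenated, labelled
   `subdomain::factor_i`.

4. **CCA.**  When a block's reduced dimension is still large relative to N
   (typical for edge data), plain PCA compresses it to `bm_target_dim`
   first.  CCA is solved by whitening each block with the inverse square
   root of its covariance (eigendecomposition; relative eigenvalue floor
   1e-10 with a hard error — no silent ridge) and SVD of the whitened
   cross-covariance.  The per-component sign is pinned deterministically
   (the subject with the largest |canonical score| scores positive,
   flipping P and Q jointly), which makes canonical variables invariant to
   input sign-flips and comparable across folds.

5. **Permutation significance.**  Rows of Y are permuted (unrestricted by
   default; whole-family exchange or within-family permutation available),
   and the null statistic is the *first* canonical correlation of each
   permuted fit — a max-statistic null, so comparing every observed rᵢ to
   it controls familywise error across components.  p-values are
   (1 + #{null ≥ rᵢ})/(1 + n_perm); the number of significant pairs is
   counted sequentially, stopping at the first non-significant component.
   Because covariances are permutation-invariant, whitening is reused and
   each permutation costs one small SVD.

6. **Stability (family-respecting CV).**  Families are assigned whole to
   folds by seeded greedy balancing (largest family first into the
   currently smallest fold, random tie-breaks).  Per fold, the *entire*
   reduction is refit on training subjects (dimensions re-estimated),
   held-out subjects are projected through training rotated loadings and
   training canonical weights, and the held-out canonical correlations
   corr(X_test A_train, Y_test B_train) are reported signed (not forced
   non-negative).  A permutation test on the projected held-out variables
   permutes rows of Q̃ against P̃ with a max-over-components null.
   Preprocessing is performed once on the full cohort before splitting
   (matching the pipeline's narrative order); a fold-wise de-confounding
   option exists for stricter separation.  Loadings are aggregated across
   folds after matching components by index and sign-aligning each fold to
   the first via the correlation of their observed-variable loading
   vectors; occurrence counts in the per-fold top-T (default T = 20,
   reporting threshold ≥ 2 occurrences) with per-item mean and SD
   summarize stability.

7. **Connectome utilities.**  A stack of symmetric R × R matrices unfolds
   to one column per ordered (region, partner) pair, so each undirected
   edge appears in the sub-domains of both its endpoints; the redundancy
   is absorbed by the per-region reduction, and constant diagonals are
   removed by QC's zero-sd rule rather than special-cased.  The
   Tikhonov-regularized partial correlation (precision of covariance +
   ρ·mean-diagonal·I, normalized and negated) reproduces the standard
   construction of such matrices from region time series.  Edge-level
   canonical loadings are symmetrized by averaging the two column copies,
   modulated by the sign of the group-mean correlation, and summarized per
   region by the mean of the top-n positive and negative modulated entries
   ("CCA strength").

## Synthetic data: what it emulates and what it does not

`synthgen` generates behaviour-like tables (per-domain low-rank signal with
orthonormal, optionally sparsity-masked loadings, plus i.i.d. Gaussian
noise), connectivity stacks (subject-weighted symmetric rank-1 patterns
u_k u_kᵀ plus symmetric noise, unit diagonal), Gaussian confounds with
linear effects on a random half of the columns, family structure (shared
random intercept on the latent scores, sd 0.4 by default, variance-
normalized), missingness, and sign-scrambled columns.  Cross-block modes
are planted exactly: with a shared mode variable z and
c = sqrt(ρ/(1−ρ)), setting f = (f0 + c z)/sqrt(1+c²) on both sides makes
the population canonical correlation of the factor blocks exactly ρ;
observation noise attenuates the observed-level value by
1/sqrt(1 + σ²_noise/σ²_signal) per block (reported in the truth object).

The desk-scale preset mirrors the shape of a large population study: 14
behaviour sub-domains (218 variables; per-domain factor counts between 1
and 14, summing to 62), a 20-region connectome with 5 global patterns,
N = 500, two planted modes at ρ = 0.75 and 0.55 carried by the leading
cognition factor and the tobacco-use factor.  Two modes at these strengths
are what is reliably detectable at N = 500 with ~35-factor blocks (the
permutation null of the first canonical correlation sits near 0.45 there);
they stand in for the handful of moderate brain-behaviour modes such
studies report.

Not emulated: fMRI time-series dynamics (the connectivity matrices are
drawn directly), non-Gaussian marginals beyond what rank-INT would remove,
structured (non-random) missingness, confound-by-signal interactions, and
realistic family pedigrees (families are exchangeable blocks with a single
shared intercept).  Passing tests therefore demonstrate correctness of the
algorithms and calibration of the inference under the latent-factor model,
not robustness to every pathology of real cohort data.

## Numerical choices and problem sizes

- SVD/eigendecompositions via LAPACK through numpy; pseudo-inverse via
  `numpy.linalg.pinv` (tests cross-check against an independently coded
  SVD-based pseudo-inverse at 1e-10).
- Whitening eigenvalue floor 1e-10 (relative): below it CCA raises and
  advises further reduction.
- Varimax: tolerance 1e-6, max 1000 iterations, Kaiser normalization;
  zero-norm rows are left unscaled.
- Ties: average ranks in the Blom transform; smallest k at equal PRESS;
  smallest k among tied dimension votes; random (seeded) tie-breaks in
  fold balancing.
- Degenerate inputs: single-variable domains fix k = 1; zero-variance
  variables get loading 0 with a warning; degenerate projected canonical
  variables get held-out correlation 0 with a warning.
- Seeds: every stochastic routine takes an integer seed
  (`numpy.random.default_rng`, PCG64).  Dimension-estimation repeat i uses
  `seed + i`; sub-domain d offsets its seed by 7919·d; CV fold f by
  104729·(f+1); all reduced modulo 2³¹.
- Test and acceptance problem sizes are chosen for minutes-scale runtimes
  on one core: dimension recovery at N = 250, P = 12, rank 3, 11 repeats;
  type-I calibration with 199 permutations × 300 replicates; stability at
  N = 2000 with 3 dimension-estimation repeats and 199 permutations; the
  full-pipeline run at N = 500 with 5 repeats and 499 permutations.
  Defaults in `PipelineConfig` (50 repeats, 10,000 permutations) reflect
  full-scale practice.

## Known limitations

- The leave-one-column PRESS loop is quadratic in the sub-domain width P
  per candidate dimension; very wide sub-domains (hundreds of variables)
  are slow at 50 repeats.
- Dimension estimates are conservative for factors whose signal sd
  approaches the noise sd; weak planted factors are absorbed rather than
  counted (visible in the preset, where 62 true factors yield ~39 chosen).
- The exchangeability-block permutation requires equal block sizes for
  whole-block exchange; unequal families must use within-block permutation,
  which tests a narrower null.
- Canonical components are matched across CV folds by index only; modes
  that swap order between folds blur the occurrence summaries.
- The null-eigenspectrum crossing is a diagnostic, not a selector.
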