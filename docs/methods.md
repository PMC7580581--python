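# Methods

This note documents the statistical procedures implemented in `furscent`,
the choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Preprocessing

Aligned peak tables are preprocessed in a fixed order:

1. **Singleton exclusion** (`filter_rare_compounds`, default
   `min_samples=2`): a compound observed in a single sample carries no
   information about group structure and is more likely an alignment
   artifact or contaminant than a shared signal.
2. **Relative abundance** (`to_relative_abundance`): each sample is scaled
   to sum to 100. The *percent* scale rather than proportions is deliberate:
   log(x+1) is scale-sensitive, and percent is the convention of the
   alignment toolchain these tables typically come from. A sample with zero
   total abundance is rejected by name.
3. **log(x+1)** (`log_transform`): natural log; zeros (undetected peaks)
   map to zeros, and the transform compresses the dominance of the largest
   peaks before computing distances. The base is a convention choice —
   Bray–Curtis ranks, and hence NMDS and permutation p-values, are only
   affected through distance magnitudes.

Filtering precedes normalization so removed singletons do not contribute to
the percent denominators. The `unit_state` tag on the matrix
(`raw → relative_percent → log_relative`) makes double application an error
rather than a silent corruption.

## Bray–Curtis and Gower centering

`bray_curtis` computes d_ij = Σ|x_im − x_jm| / Σ(x_im + x_jm) (via scipy's
`pdist`), in [0,1] on nonnegative data, by default insisting on
log-transformed relative abundances. A pair of all-zero fingerprints makes
the denominator vanish and is rejected.

All variance partitioning works on the Gower-centered matrix
G = J(−½D²)J, J = I − 11ᵀ/n, whose trace is the total sum of squares of the
distance decomposition. Bray–Curtis is generally not Euclidean-embeddable;
`is_euclidean_embeddable` reports the minimum eigenvalue of G as a
diagnostic.

## Sequential PERMANOVA with nested terms

`permanova` partitions tr(G) by sequential (Type I) projection: for
cumulative design matrices X₀ (intercept) ⊂ X₁ ⊂ … ⊂ X_k with hat matrices
H_j (built from an SVD orthonormal basis, so rank deficiency from redundant
dummy columns is handled exactly),

    SS_j = tr(H_j G) − tr(H_{j−1} G),    df_j = rank(X_j) − rank(X_{j−1}),
    pseudo-F_j = (SS_j/df_j) / (SS_res/df_res),    R²_j = SS_j / tr(G).

Term R² plus residual R² sum to 1 by construction (tested to 1e-8, and
verified term-by-term against vegan's `adonis2(…, by="terms")`).

A nested factor (family within colony) is encoded as parent:child
interaction labels entered after the parent's own term, giving it
df = (#families − #colonies).

**Permutation null.** Significance uses free permutation of samples
(equivalently, simultaneous row/column permutation of G), one shared
permutation stream for all terms, with the add-one convention
p = (#{F_perm ≥ F_obs} + 1)/(B + 1); ties count toward the numerator
(conservative). When n! does not exceed the requested count, the null is
enumerated exhaustively and p is the exact proportion over all n!
permutations (identity included). Free permutation is the default of the
standard distance-based ANOVA toolchain; restricted schemes are deliberately
not the default — comparisons "within strata" are handled explicitly by
subsetting in `pairwise_permanova`.

`permanova_oneway_oracle` implements the independent group-sum identity
(SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij) and exists purely as a
cross-check on the projection route.

## Homogeneity of dispersions

`betadisper` embeds the samples by PCoA, keeping negative-eigenvalue
("imaginary") axes, and computes each sample's squared distance to its group
center as (squared real-axis distance) − (squared imaginary-axis distance);
negatives arising from this correction are clamped to zero and counted
(`n_clamped`). The resulting distances are compared across groups by a
one-way ANOVA F with (k−1, n−k) df. Defaults are the group **centroid** and
the **classical F** p-value; a spatial-median center (Weiszfeld iteration on
the real axes, imaginary center at the group mean) and a label-permutation
p-value are available as options. On Euclidean-embeddable input the
procedure reduces exactly to distances-to-centroid in the original
coordinate space (tested to 1e-8, and against vegan's
`betadisper(…, type="centroid")`).

## Pairwise comparisons and count tests

`pairwise_permanova` subsets the distance matrix to every unordered pair of
grouping levels (the grouping may be a composite factor, e.g. colony × age),
runs a one-way PERMANOVA per pair, and Bonferroni-corrects:
p_corr = min(1, p × m) with m the number of pairs actually tested. Pairs in
which a level has fewer than two samples are skipped with a log note.

`compare_counts` compares per-sample compound richness between groups with
Student's equal-variance t (two groups) or one-way ANOVA.

## PCoA and NMDS

`pcoa` eigendecomposes G; eigenvalues within ±1e-9 (relative) of zero are
dropped, axes are scaled by √|λ|, and negative-eigenvalue axes are retained
separately for the dispersion correction.

`nmds` minimizes Kruskal stress-1,
√(Σ(d_ij − d̂_ij)² / Σ d_ij²), where d are configuration distances and d̂
their monotone regression on the input dissimilarity order. Details:

- **Isotonic fit** by pool-adjacent-violators with **primary tie handling**:
  tied input dissimilarities impose no order constraint among their fitted
  values (ties are broken by the current configuration distances before the
  PAVA pass). Ties are pervasive in sparse Bray–Curtis data, which makes the
  secondary (forced-equal) approach needlessly restrictive.
- **Configuration updates** by the Guttman transform. Guttman steps
  guarantee descent of raw stress, not of normalized stress-1, so each step
  is accepted only if stress-1 decreased; otherwise the previous
  configuration is kept and the start terminates. The per-iteration stress
  trace is therefore non-increasing by construction (and asserted in tests).
- **Convergence** at stress change < 1e-6 or 300 iterations; **restarts**:
  the first start is the PCoA configuration, the rest (default 19) random
  Gaussian configurations from the seed; the lowest-stress solution wins.
- Output coordinates are centered and scaled to RMS inter-point distance 1;
  stress-1 is invariant to this normalization and is recomputable from the
  returned coordinates.

NMDS is visualization-only: no downstream statistic consumes its
coordinates. The embedding dimension defaults to 2 and no automatic
dimension selection is attempted.

## Bootstrap effect-size standardization

Permutation p-values cannot be compared across studies with different n, so
effect sizes are standardized by resampling to a common design:
`bootstrap_effect_sizes` draws, per replicate, `pairs_per_colony` (default
15) families with replacement independently within each of two colonies,
carries every member of a drawn family (twin trios enter whole, so replicate
size can slightly exceed 60), recomputes Bray–Curtis on the resampled rows,
refits the model, and records each focal term's R².

Choices that matter:

- **The resampling unit is the family, not the individual.** The family
  term requires intact mother-offspring units; resampling individuals would
  destroy the very structure being measured, and 15 pairs × 2 colonies
  reproduces the standard 60-individual design.
- **Duplicated families receive fresh labels per copy**, keeping the family
  df at (#families − #colonies) in every replicate and preventing duplicate
  (distance-zero) rows from inflating within-family SS under one label.
- **Preprocessing is done once on the full dataset, not per replicate** —
  per-sample normalization is resampling-invariant, and refiltering
  compounds per replicate would mix compound-set churn into the R²
  distribution.
- **Per-replicate permutation p-values are skipped** (permutations=0): only
  R² is consumed.

Each term's replicate distribution is summarized by `summarize_bootstrap`
(median, quartiles, 1.5×IQR whiskers clipped to the observed range,
2.5/97.5% quantiles with linear interpolation) and by the
**maximum-density estimate**: the mode of a Gaussian KDE with Silverman
bandwidth evaluated on a 512-point grid spanning [min − 3h, max + 3h], ties
broken toward the smaller value.

## Synthetic data generator

`generate_dataset` draws per-compound baselines b_m ~ N(base_log_mean,
base_log_sd) over a pool of `pool_size` (default 200) compounds, adds
independent normal effects per colony (σ_colony), family (σ_family) and
individual (σ_individual) on the log scale, and detects compound m in
individual i with probability logistic(detection_slope · (L_im − τ)).
Abundance is exp(L_im) when detected, 0 otherwise — so presence/absence and
abundance carry correlated group signal, as in real sparse fingerprints.

τ is solved once per dataset (Brent's method over a Gauss–Hermite
quadrature of the logistic-normal expectation, using the realized baselines
and the combined effect sd) so that the expected per-sample richness equals
`mean_detected` (default 42). Solving against the realized baselines keeps
the realized mean count tightly on target across seeds while leaving
per-sample counts random around it. In the rare event a sample detects
nothing, its strongest latent compound is forced on — an all-zero
fingerprint is not a usable sample.

Defaults (σ_colony = 0.4, σ_family = 0.6, σ_individual = 1.0, slope = 1.5,
base log mean 2.0, sd 1.0, twin probability 0.02) were chosen to give a
realistic sparse fingerprint with a colony effect of a few percent of total
variance and a clear family signal. `study_design_config` provides three
design presets: `replication` (2 colonies × 25 mother-pup families, exactly
one twin trio → 101 samples), `original` (21 + 20 families → 82 samples) and
`six_colony` (pups only, 25 + 25 + 4 × 15 → 110 samples). The config's
`n_twins` field forces an exact twin count for these presets;
`twin_probability` governs the random mode.

**What the generator does not emulate:** retention-time drift and alignment
error, co-eluting peaks, batch effects, heavy-tailed or correlated compound
abundances, and compound-specific detection floors. The per-sample richness
spread it produces (s.d. ≈ 5–6 compounds around the mean of 42) is narrower
than the spread typical of field swab data, where sample quality varies far
more; only the mean richness is calibrated. Tests passing on this
generator therefore demonstrate the correctness and calibration of the
*statistics* (type-I error, SS accounting, bootstrap self-consistency,
monotone response of R² to the variance knobs) — not that any particular
field dataset will show a given effect size.

## Numerical choices and degenerate inputs

- Rank decisions in design matrices use an SVD threshold (1e-8 relative);
  a term adding no estimable df is an error, not a silent drop.
- PCoA eigenvalues within ±1e-9 (relative) of zero are treated as zero.
- Distance matrices must be symmetric with zero diagonal to 1e-12.
- `permutation_pvalue` is bounded below by 1/(B+1); exhaustive enumeration
  returns the exact null proportion instead.
- Degenerate NMDS input (all distances equal) is rejected; a collapsed
  configuration terminates the affected restart.
- Negative squared distances from the imaginary-axis correction in
  `betadisper` are clamped to zero and reported via `n_clamped`.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the pipeline derives per-stage seeds from the master seed by
  hashing the stage name, so adding a stage never perturbs earlier streams.

## Problem sizes in the shipped analyses

The acceptance script and test suite run the full method at desk scale:
9,999 permutations for reported p-values (the permutation p is stable across
99,999/9,999/999 for these designs), 500 bootstrap replicates, and 199
permutations × 500 replicates for the type-I-error calibration. These sizes
are the package's own defaults for routine reanalysis; the library defaults
(99,999 permutations, 5,000 replicates) match common publication practice
and are used by simply not overriding them.

## Known limitations

- Restricted (within-stratum) permutation is not implemented as a default
  scheme; stratified questions are addressed by explicit subsetting.
- The spatial-median dispersion center is a Weiszfeld approximation on the
  real PCoA axes, not the full generalized median on the corrected metric.
- Bonferroni is the only multiplicity correction offered.
- Bootstrap intervals are plain percentile summaries (no BCa correction),
  and no formal cross-study test of R² equality is provided — distributions
  are compared descriptively.
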