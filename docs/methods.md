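# Methods

This note documents the models, conventions, and numerical choices behind
`restspeech`, and what the synthetic-data tests do and do not establish.

## Measures

### Connectivity

Edges are Fisher-z transformed Pearson correlations between node time
courses, with the diagonal and negative entries set to zero. Clipping is
applied after the transform; since atanh is monotone and sign-preserving,
clipping r before transforming is equivalent, but the post-transform order
is fixed for auditability. Correlations numerically at |r| ≥ 1 are clamped
to 1 − 1e−12 with a warning; a constant node signal is an error, not a NaN.
Node order everywhere is atlas file order, and all edge vectors inherit it.

### Segregation

S = (W − B)/W per network, with W the mean z over unordered within-network
pairs and B the mean z over all pairs linking the network to any other.
Zero-clipped edges participate in W and B as zeros — they were set to zero,
not removed, and dropping them instead would change both means. Whole-brain
segregation is the unweighted mean of the per-network S values; a
node-weighted mean is available (`node_weighted=True`) but not default.
W = 0 raises rather than returning an undefined ratio.

Outlier screening uses the |x − mean| > 2.5·SD rule (n−1 SD), computed over
the full sample; negative values of sign-meaningful measures (language
segregation, whole-brain ALFF) are additionally flagged. Flagged
participants are dropped from *all* downstream analyses so every pairwise
analysis shares one participant set. A per-group variant of the screening
statistics is a one-line change around `flag_outliers` if needed.

### ALFF

The node signal is linearly detrended, Fourier transformed, and the
one-sided amplitude spectrum a_k = 2|X_k|/N is averaged over bins with
0.008 ≤ k/(N·TR) ≤ 0.09 Hz, both edges inclusive, DC excluded (at the
default N = 240, TR = 2.5 s this is bins 5–54, i.e. 50 bins). Any
consistent DFT normalization would do; this one is fixed so results are
bit-reproducible and so that a unit-amplitude in-band sinusoid contributes
exactly 1 at its bin. A 1e−9 epsilon guards the closed band edges against
floating-point placement of the frequency grid. Group-level ALFF values are
standardized across participants separately for the language mean and the
whole-brain mean; node-level ALFF feeds the dissimilarity analyses
unstandardized (Euclidean distances are taken on raw node profiles).
Averaging first and standardizing second was chosen because the
standardization is a between-participant operation; the opposite order is
not implemented.

### Speech factor

Variables are standardized and a single common factor is extracted by
iterated principal-axis factoring (SMC-initialized communalities; the
initialization falls back to the largest absolute off-diagonal correlation
when the correlation matrix is singular, which keeps the perfectly
collinear degenerate case well-defined). PAF was chosen because it is
deterministic and dependency-light; the estimator behind the field's usual
R workflow is not uniquely pinned down, and at these communalities the
estimators agree far inside the reported tolerances. Varimax is executed
even for the single-factor case (where it is the identity) so the code path
is exercised. Kaiser retention is judged on the eigenvalues of the full
correlation matrix; if more than one eigenvalue exceeds 1 the fit warns and
still extracts one factor, since the composite is the object of interest.
Scores are Thurstone regression scores Z R⁻¹ λ (pseudo-inverse when R is
singular), signed so the MLU loading is positive, re-centered to exact zero
mean. Adequacy checks: Bartlett sphericity −(n−1−(2p+5)/6)·ln det R with
p(p−1)/2 df, KMO from squared correlations vs. squared anti-image partial
correlations, VIF from the diagonal of R⁻¹, Mahalanobis outlier
probabilities from the chi-square with p df.

### Dissimilarity structure

Connectivity dissimilarity is 1 − r between edge vectors (range [0, 2]);
feature dissimilarities are Euclidean, which reduces to |Δ| for scalars
(language segregation, speech score). Whole-brain segregation dissimilarity
is the Euclidean distance between the 14-long per-network segregation
vectors — the vector reading of "across the whole-brain networks"; a scalar
|Δ whole-brain S| variant exists behind `scalar_wb_segregation_rdm` because
the convention is genuinely ambiguous. Integration standardizes each RDM's
upper triangle (mean 0, SD 1 over the n(n−1)/2 pairs, n−1 denominator,
diagonal excluded) and averages the three entrywise. Pair tables enumerate
unordered pairs in lexicographic id order with comparison-group codes
−0.5 / 0 / +0.5 (within-younger / within-older / between).

## Inference

* Welch t-tests with Satterthwaite df for all group comparisons.
* Comparison-group ANOVA: one-way fixed-effects F on the standardized
  dissimilarity, residual df = pairs − 3; Tukey HSD follow-ups (the
  pairwise-comparison method is not otherwise pinned down).
* k-NN: stratified seeded 70/30 split, k = ⌊√n_train⌋, Euclidean distance,
  majority vote; vote ties (k = 6 is even) are broken by the single nearest
  neighbor. With the 62-participant default cohort the split is 43/19
  rather than a literal 45/20 — the rule follows the stated fractions of
  the supplied cohort.
* Moderated regressions: OLS of outcome on group code, predictor, and their
  product; continuous variables standardized internally, group codes passed
  through on their ±0.5 scale so their coefficients stay interpretable.
  Pair-level regressions treat pairs as independent observations — the
  parametric p-values there inherit the dyadic dependence of pairs and are
  anti-conservative, which is exactly why the permutation test exists.
* Permutation tests (B = 1000 by default) permute *participant-level*
  speech scores and, for pair-level designs, rebuild the speech
  dissimilarity column from the permuted scores before each refit
  (Mantel-style), respecting the dependence between pairs sharing a
  participant. p = (1 + #{|t*| ≥ |t_obs|})/(B + 1), which cannot return 0.
* Slope comparisons between groups use z = (b₁ − b₂)/√(se₁² + se₂²) with a
  two-sided normal p — the standard independent-coefficient comparison.

## Synthetic cohort generator

Each node signal is a sum of equal-amplitude sinusoids at the DFT-aligned
frequency bins inside the 0.008–0.09 Hz band with i.i.d. uniform phases,
giving exactly unit variance and exactly zero out-of-band energy — no
digital filter is needed and ALFF is analytically checkable. A node in
network m is

    x = amp · (√b·G + √(w_m − b)·L_m + √(1 − w_m)·E),

with G a global signal, L_m a network signal, and E node noise (all
independent unit-variance band-limited signals), so population correlations
are w_m within network m and b between networks, and ALFF is exactly
proportional to amp. Participant-level heterogeneity comes from Gaussian
jitter on w (clipped to [b, 0.98]) and multiplicative Gaussian jitter on
amp, so that the group amplitude scale acts as an exact gain.

Defaults emulate the study conditions the analysis assumes: 38 younger and
24 older adults, 240 volumes at TR 2.5 s, a 264-node atlas with 33
exclusions, 12 base networks plus 9 left and 9 right language nodes. Group
effects default to lower within-network correlation (0.50 → 0.32) and lower
amplitude (1.0 → 0.70) in the older group, with the language network's
correlation and amplitude group-invariant — the stable-language-network
regime. Between-network correlation is 0.10 in both groups. Where no
external value pins a parameter (jitter SDs 0.05 and 0.08, coupling 0.6),
values were chosen once to produce large, cleanly detectable group effects
at n = 38/24 with realistic overlap between individuals, and are not
revisited.

Speech measures are λ·latent + noise_sd·√(1 − λ²)·ε on the standardized
scale — so with unit-variance latent and noise_sd = 1 the population
loading of each measure is exactly λ — then mapped affinely to plausible
observable scales (MLU ≈ 8 ± 2 morphemes, disfluency ≈ 0.15 ± 0.05 clipped
to [0, 1], etc.). The default loadings (0.81, 0.63, 0.76, 0.73, −0.67 on
MLU, verbs, LCC, RE, disfluency) imply a single factor explaining 52% of
the variance. The latent factor is c·(z_seg + z_amp)/2 + √(1 − c²)·ε, where
z_seg and z_amp are cohort-standardized true whole-brain segregation and
amplitude and c is the brain–speech coupling.

Determinism: per-participant random streams are spawned from the cohort
seed via `SeedSequence(seed, spawn_key=(i,))`, so stream i does not depend
on cohort size and identical (config, seed) regenerates cohorts
bit-for-bit.

What the generator does *not* emulate: hemodynamic response shape, head
motion and physiological artifacts, voxel-level structure, spatial
autocorrelation, non-Gaussian edge-weight distributions, and any real
correspondence between node coordinates and function (the bundled atlas is
a synthetic Power-style stand-in: counts and partition match the reference
scheme, coordinates are a grid). Passing tests therefore establish that the
pipeline recovers the statistical structure it assumes — not that real
resting-state data satisfy those assumptions.

## Problem sizes in the test suite

Unit and acceptance tests run the generator at reduced node counts
(typically 60 nodes, 6 base networks, 5 language nodes) and full
participant counts, which preserves every df and pair-count property while
keeping per-cohort cost around a second; calibration suites use 300–3000
simulations with B = 200 permutations. These sizes are the package's
testing choices; all group-size- and pair-count-dependent assertions
(e.g. residual df 1767 at 60 participants) are invariant to node count.

## Known limitations

* Pair-level OLS ignores dyadic dependence by design (mirroring the
  analysis convention it implements); rely on the permutation p-values for
  inference there.
* The EFA machinery is specialized to the five speech variables; it is not
  a general factor-analysis library.
* `language_S` is only defined when the atlas designates left-language
  nodes; with none, language-level analyses are skipped rather than
  approximated.
* Right-language-network analyses are carried in the atlas but not
  analyzed, matching the analysis scope.
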