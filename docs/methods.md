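# Methods

This note documents the models, numerical choices, and limitations behind
`stoichiomap`. Notation: n proteins, m conditions, pᵢ the m-vector of
abundances of protein i across conditions, p̂ⱼ the n-vector proteome profile
of condition j, r̂ⱼ the condition-mean discriminant-space Raman coordinates.

## Synthetic study generator

The generator (`stoichiomap.datasets`) emulates a study in which bulk
proteomes are quantified under m growth conditions and single-cell Raman
spectra are measured under the same conditions.

**Conditions.** Growth rates are evenly spaced over a configurable range
(default 0.05–2.0 h⁻¹, m = 15) with a small seeded jitter at the interior
points; endpoints stay on the range boundary so the configured range is
always realized.

**Proteome.** Default n = 2058 with a planted architecture:

* *homeostatic core* (default 191 proteins): abundance aᵢ·μⱼ — a shared
  growth-law pattern (linear in growth rate, zero intercept) times a
  protein-specific amplitude;
* *fast-growth group* (default 26): aᵢ·exp(b·μⱼ) with b chosen so the
  max/min ratio across the growth-rate range is ≈ 30;
* further condition-specific groups (defaults 20, 10, 9): a pattern peaked
  in one randomly chosen condition (baseline 0.05, peak 1.0) times
  amplitudes;
* *background* (the remainder): independent log-normal patterns per
  condition.

Amplitudes are log-normal (σ = 1), giving the multi-decade dynamic range
typical of absolute proteomics; this value is a package choice, not taken
from any reference dataset. Abundance noise is multiplicative log-normal
with mean 1 and coefficient of variation `noise_cv` (default 0.1, a typical
replicate-level CV for quantitative proteomics); abundances are positive and
span decades, which makes a multiplicative model the natural choice. With
`noise_cv = 0` every within-group cosine similarity is exactly 1.

**Spectra.** Each protein gets a fixed signature of 3–8 Gaussian peaks with
centers uniform on the 700–1800 cm⁻¹ fingerprint region and widths 8–25
cm⁻¹, assembled into a non-negative channels×n matrix S with unit column
sums (signatures are abstract; no physical band assignment is attempted). A
cell under condition j measures S·p̂ⱼ·η + ε with η a per-cell log-normal
scale (CV 0.05, overall-intensity variation) and ε i.i.d. Gaussian channel
noise (sd 0.02 on the scale of the signature-averaged abundances). Default
grid: 1231 channels on 632–1862 cm⁻¹ (1 cm⁻¹ spacing); 15 cells × 3
replicates per condition. By construction the condition-mean spectra are an
exact linear function of the proteome columns when η = 1, ε = 0.

**Annotations.** The probability of an `essential` (and `coding`) flag is
logistic in the planted centrality rank percentile with a slope scaled by
`enrichment_strength ∈ [0,1]`; ortholog counts are Poisson with a
rank-increasing mean. `stochastic=False` thresholds the probabilities,
giving a noise-free monotone variant used by construction-level tests.

**What the generator does not emulate.** Instrument noise structure
(pixel-dependent sCMOS readout noise), baseline drift and cosmic rays,
biological covariance between background proteins, and — important for one
structural diagnostic, see "Limitations" — condition-dependent structure in
the background proteins, which the real proteome has but the generator
deliberately leaves as i.i.d. noise. Passing tests therefore demonstrate
correctness of the machinery under the planted model, not instrument-level
realism.

## Spectral preprocessing

Order: background subtraction → crop to 632–1862 cm⁻¹ (closed interval,
boundary channels included) → Savitzky–Golay smoothing (default window 11,
polynomial order 3; both configurable) → per-spectrum standardization to
mean 0, sd 1 (sample sd, N−1; at ~10³ channels the population/sample
distinction is negligible) → selection of the 700–1800 cm⁻¹ fingerprint
band. Standardizing on the wide crop before band selection is the default;
the reverse order is available via `standardize_after_band` since either
convention is defensible. Standardization removes laser-power and overall
intensity variation, which is why the generator's per-cell scale η is
harmless downstream.

## Discriminant analysis

`ConditionLDA` solves the between/within scatter generalized eigenproblem.
With channels ≫ cells the within-class scatter S_w is singular, so the data
are first projected onto principal components of the total scatter. The
retained dimensionality is the numerical rank (relative tolerance 1e-10)
**capped at N − c** for N cells and c classes: inside the full-rank
total-scatter subspace S_w still has rank at most N − c, and without the cap
the pencil (S_b, S_w) is ill-posed. Axes are sorted by eigenvalue with a
stable sort; each axis's sign is fixed so its largest-magnitude loading is
positive. Scores are not whitened — downstream quantities (Ω_B) depend only
on the affine span of the condition means, so the scale convention is
irrelevant there. Degenerate inputs (identical class means) yield zero axes
with an explicit warning rather than an exception.

## Raman→proteome correspondence

Per-protein OLS of abundance on [1, r̂ⱼ(1..K)] with K = 4 by default (the
leading axes carry essentially all condition discrimination; the full
K = m−1 model is supported and is fitted as the minimum-norm least-squares
solution when a leave-one-out fold leaves it underdetermined). Predictions
are not clipped at zero: negative estimates are meaningful residual
diagnostics. The leave-one-out report carries both the per-fold predictions
and the average of the m leave-one-out coefficient matrices; this averaged B
is the default input to the coefficient-proportionality analysis and to Θ
(a full-data fit is available by flag).

The permutation test draws permutations uniformly (identity included; with
~10⁵ draws from 15! duplicates are negligible and no deduplication is done)
and uses the add-one convention p = (1 + #{σ : error_σ ≤ observed})/(1 +
n_perm), so p ∈ (0, 1] always. Four distance measures are provided:
squared Euclidean (PRESS), Manhattan, cosine distance, and 1 − Pearson.

Ω_B coordinates βᵢₖ = bᵢₖ/bᵢ₀ are defined only for proteins with
|bᵢ₀| ≥ 1e-8 × median|b₀|; the rest are excluded explicitly and never
returned as NaN.

## Stoichiometry-conservation network

The cosine matrix A gets an exact unit diagonal (a self-loop per node); for
non-negative data all entries lie in [0, 1] and the degree dᵢ ∈ [1, n].
SCG extraction uses edges with A_{ij} ≥ threshold (ties at the threshold
included; default 0.995), keeps connected components with at least two
members, and orders them by size descending with ties broken by smallest
member index, so "SCG 1" is always the largest group.

csLE solves the symmetric problem D^{-1/2}AD^{-1/2} (same spectrum as
L_rw = I − D⁻¹A; eigenvectors map back through D^{-1/2}), avoiding a
non-symmetric solver. Eigenvectors are scaled to unit L2 norm and
sign-fixed like the LDA axes. Because rank(A) ≤ min(m, rank(P)), exactly
min(m, rank(P)) − 1 Laplacian eigenvalues lie strictly in (0, 1), one is 0
(constant eigenvector), and the rest equal 1; `n_informative_` reports how
many returned axes are informative — for a fully conserved (rank-1)
proteome it is 0 and the embedding carries no structure, which is the
correct degenerate answer.

The PCA comparison baseline applies PCA to L2-normalized expression rows so
it acts on the same directional information as A.

## Structure comparison

The appendix-level analytic derivation of Θ is not reproduced; Θ is defined
**operationally** as the orthogonal polar factor of the least-squares linear
map between the m-dimensional augmented representations [v₀ | csLE
coordinates] and [1 | Ω_B], restricted to proteins present in both. This is
a substitute construction: it agrees with the analytic Θ whenever the two
representations are related by an exact orthogonal map, and degrades
gracefully otherwise.

Closeness to the identity treats the Hadamard square Θ∘Θ (row and column
sums exactly 1, total mass exactly m, by orthogonality) as a 2-D histogram
over index coordinates and computes the weighted Pearson correlation of row
with column index; weights may be any non-negative reals. The identity
scores exactly 1, the reversal permutation exactly −1. The null is 1000
(configurable) Haar-distributed orthogonal matrices from QR with the
R-diagonal sign correction. Two further diagnostics — cumulative squared
mass over diagonal bands from the corners inward, and over leading principal
submatrices — are reported for Θ, the identity, and the null mean.

The d–g proportionality uses the analytic slope ((Σⱼdⱼ)/m)^{1/2}, never a
fitted one; for the fully conserved uniform proteome (dᵢ = n, gᵢ = √m) the
residuals vanish identically. Residuals are correlated (Spearman) with the
growth rate of each protein's most-expressed condition.

Condition subsampling reruns LDA → B → Ω_B (all subset axes, leave-one-out
averaged) and csLE on each random condition subset and reports the Θ
closeness and its null percentile per subset size.

## Annotation statistics

The Brunner–Munzel test is implemented from first principles: pooled and
within-sample midranks, the rank-variance estimator, and the
Satterthwaite-type degrees of freedom, targeting P(X>Y) + ½P(X=Y). Two
degenerate regimes are distinguished: **all pooled ranks tied** (no ordering
information) is rejected with an explicit error, while **complete
separation** (zero rank variance with estimate exactly 0 or 1) returns a
±∞ statistic and a one-sided p of 0 or 1 with a warning — the
t-approximation is undefined there, and separation is the strongest possible
ordering evidence. Binned fraction curves rank genes by score descending
(stable ties) into near-equal classes, spreading the remainder over the top
classes so bin sizes differ by at most one. Quartile comparisons are
reciprocal: attribute split by score rank and score split by attribute rank,
both reported.

## Problem sizes used in the test suite

The unit tests run a reduced study (8 conditions, 120 proteins, 64 cells,
300 channels) chosen so the full suite completes in well under a minute
while every planted structure remains recoverable; the acceptance-level
checks that concern counting identities (14 LDA axes, 105 condition pairs,
d = n = 2058) run at the study's nominal scale, and the SCG-recovery and
condition-subsampling checks run at the full default generator scale.

## Known limitations

* Θ's closeness score is not comparable across dimensions: the Haar null
  concentrates toward 0 roughly like 1/m, so raw closeness values shrink
  with m even at fixed correspondence quality. Compare against the null at
  the same size (the reported percentile), not across sizes.
* In the synthetic emulation the planted structure spans only ~6
  condition-space dimensions; higher csLE/LDA axes are ordered by noise in
  both spaces and cannot align. Raw Θ closeness therefore *decreases* with
  the number of subsampled conditions beyond the planted dimensionality,
  although the null percentile stays high at every size. Real proteomes,
  with structured condition dependence in all genes, need not behave this
  way.
* The planted core follows a strictly one-dimensional growth law, so its
  regression coefficients on discriminant axes orthogonal to growth are ~0
  and the through-origin proportionality R² is only meaningful on the
  growth-dominated leading axis.
* No baseline correction beyond background subtraction, no cosmic-ray
  removal, and no pixel-noise filtering are implemented; inputs are assumed
  to be already reduced to per-cell spectra.
* Annotation enrichment is a logistic toy model keyed to the planted
  centrality ordering; it validates the statistics, not any biological
  claim.
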