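# Methods

This note documents the models, estimators, defaults and numerical choices
behind `circapal`, and what the synthetic studies do and do not demonstrate.

## Data model

An expression matrix holds genes × samples values bound to a *time design*:
an ordered grid of sampling times within one period (default period hint
24 h) with a fixed number of replicates per time point. The built-in grid is
the 18-point design t = {0.25, 1, 2, 4, 6, 8, 10, 11, 11.75, 12.25, 13, 14,
16, 18, 20, 22, 23, 23.75} h with 3 replicates (54 samples), denser around
the light/dark transitions at 0 and 12 h. Samples are time-major by default;
an explicit sample→(time, replicate) order can be supplied. Missing values
are not supported (errors, not imputation); duplicate gene ids error by
default with an opt-in mean-collapse. Gene identifiers match by exact string
equality (optional case-folding); probe→gene mapping is the caller's
responsibility via a two-column mapping file.

## Pathway activity levels

Each pathway's submatrix (genes mapped by identifier intersection, at least
`min_pathway_size` = 5 of them — below that an SVD summary and a size-matched
null are not meaningful) is row-z-scored (sample sd, ddof = 1; the choice of
ddof cancels everywhere downstream because correlations and variance
*fractions* are scale-invariant). The PAL is the first right singular
vector, the gene weights the first left singular vector, and

    f_P = σ₁² / Σ σ_g²

with the sum over all min(k, t) singular values (terms beyond the rank are
zero). Full `numpy.linalg.svd` is used — matrices are at most a few hundred
by 54, so randomized approximations would add nondeterminism for no gain.
Singular-vector sign is arbitrary; for reproducibility the component is
canonicalized so the gene with the largest |weight| has a positive weight
(ties: lowest row index). Weights and activity always flip together, so the
rank-1 reconstruction is invariant. A `reference_correlation` mode re-aligns
a PAL against an external profile instead.

## Significance of f_P

Null: gene sets of the same size k drawn uniformly without replacement from
all measured genes (the pathway's own genes are *not* excluded by default —
the null asks "what does a random set from this matrix achieve", and
excluding members is a config toggle), f_P computed on the same matrix,

    p = #{null f_P ≥ observed f_P} / n_perm .

Ties count against the pathway ("≥", conservative). Default n_perm = 10 000;
the test suite uses 200–500 draws with correspondingly loose Monte-Carlo
expectations. Implementation note: z-scoring is per-row, hence independent
of which rows a draw selects, so the matrix is normalized once and each
draw's squared singular values are read off the eigenvalues of its t × t
Gram matrix, batched with `numpy.linalg.eigvalsh`. This is algebraically
identical to a per-draw SVD and is unit-tested against one. Constant genes
sampled into a draw are dropped from that draw when ≥ 2 usable rows remain,
else the draw is redone (both logged). Randomness: one seed, with per-pathway
substreams derived from (seed, pathway index), so results do not depend on
the order pathways are processed. Pathways pass the filter when p < 0.05
(strict). No multiple-testing correction is applied across pathways; reports
should say so.

## Circadian classification

The model is A·sin(B·t + C): amplitude, angular frequency (rad/h), phase.
A 24-h rhythm has B = 2π/24 ≈ 0.2618; the acceptance band B ∈ [0.24, 0.28]
is applied *after* fitting with B free, so non-circadian periods (e.g. 12 h)
are fitted well and then rejected. The circadian call requires both the band
and Pearson r(model, data) ≥ 0.8. Profiles are mean-centered before fitting;
the model carries no intercept. Canonical form: A ≥ 0, C ∈ (−π, π] (the
(A, B, C) ≡ (−A, B, C + π) degeneracy is folded into the phase).

### Fitting algorithm

At fixed B the model is linear in (a, b) = (A cos C, A sin C) through
a·sin(Bt) + b·cos(Bt), so the inner problem is solved exactly by 2×2 normal
equations (variable projection) and only B requires search. This replaces
multi-start over amplitude/phase — with the linear subproblem exact, such
starts are redundant — by a dense frequency grid (B ∈ [0.02, 1.30], step
0.005, i.e. periods ~5 h to ~300 h; the step is far below the ~2π/24 ripple
spacing of the SSE landscape on a 24-h record) followed by bounded scalar
refinement in the winning basin. The procedure is deterministic; a
`b_starts` argument restricts the search to given starting frequencies, and
the grid provably never does worse than any such restriction.

One subtlety: on an irregular grid, sin(Bt) and cos(Bt) have nonzero sample
means, so the no-intercept least-squares frequency is biased by up to
~0.016 rad/h even for exact signals (the centered data contain a constant
residual the model cannot represent). A free intercept removes the bias but
harms noisy-data behaviour: "slow trend + offset" sinusoids gain enough
freedom to steal the global optimum from the genuine oscillation, pulling
fitted frequencies out of the band. The estimator therefore selects the
frequency basin with the no-intercept objective and then polishes B with an
intercept-augmented objective *only when the intercept is statistically
warranted* — a nested-model F-test (α = 0.01) at the selection optimum. For
exact or near-exact signals the offset is essentially the whole residual
(F → ∞) and the polish recovers B to better than 1e-3; for noisy profiles
the intercept is insignificant and the plain sinusoid estimate stands.

### What is fitted for genes vs pathways

Gene-level classification fits each gene's profile over **all samples**
(time points repeated per replicate); PAL-level classification fits the
**replicate-averaged** 18-point activity profile (replicates are averaged
for clustering, and the centroid fits operate on averaged profiles, so one
convention covers all pathway-level fits). The gene-level choice matters:
averaging first reduces noise by √3 and would shift the entire gene-level
noise response (the 50 %-circadian crossover of the synthetic study moves
from noise level ~17 to ~30), making gene- and pathway-level detection far
less distinguishable. Fitting genes per sample reproduces the intended
regime: genes collapse while the 45-gene PAL, which pools √45-fold more
information, keeps its rhythm.

## ANOVA filter, sign alignment, consensus clustering

* **ANOVA**: one-way fixed effects on the raw per-sample PAL with time point
  as the 18-level factor and replicates as the error term
  (`scipy.stats.f_oneway`); keep when p < 0.01. Degenerate inputs: a
  constant PAL gets p = 1 (dropped); exact group differences with zero
  within-group scatter get p = 0. Averaging happens *after* this filter.
* **Sign alignment**: the reference is the first principal direction of the
  row-centered profile matrix, oriented with the majority sign so an
  already-consistent set is untouched; profiles anticorrelated with it are
  negated, essentially-uncorrelated ones (|r| < 1e-12) are left alone and
  logged. Globally negating any input PAL changes nothing downstream.
* **Ensemble**: every (family, metric, k) combination votes, k over the
  configured range (default 2–8, clipped to n−1). Distance-based families —
  agglomerative hierarchical (average linkage), divisive hierarchical
  (DIANA-style splinter splitting), k-medoids (deterministic BUILD + swap) —
  run under Euclidean, Manhattan and correlation (1 − r) distances;
  centroid/model-based families — k-means, a 1 × k batch SOM (codebook
  initialized along the first principal component), Gaussian mixture
  (diagonal covariance, reg 1e-6) — are Euclidean-only, since their
  objectives are defined in Euclidean geometry. A failed run (e.g. mixture
  non-convergence) is logged and excluded from the denominator; > 50 %
  failures is an error. The agreement matrix holds co-clustering
  frequencies; it is symmetric, unit-diagonal, invariant to label
  permutations within any run, and deterministic given the seed.
* **δ-consistency**: a pairwise agreement a is ambiguous when
  1 − δ < a < δ (δ = 0.65). Items are removed greedily — most ambiguous
  partners first, ties by lower mean agreement then name — until no
  ambiguous pair remains. Greedy removal is a documented stand-in for the
  consensus literature's unspecified removal order; it guarantees the
  invariant (asserted post hoc) but not minimality of the removed set.
* **Final partition**: average-linkage hierarchical clustering on
  1 − agreement; k chosen over the range by maximum mean silhouette on that
  distance (ties to the smaller k); centroids are mean aligned profiles,
  each sinusoid-fitted. Note that when the ensemble is forced to vote at k
  values incompatible with the true group structure, edge members of tight
  groups accumulate ambiguous agreements and are (correctly) removed — the
  δ rule trades recall for confidence, which is why the retained set is a
  subset of the filtered pathways, not all of them.

## Synthetic studies

Generator: g(t) = β·cos(ωt + φ) + ε per gene and sample, with defaults
n_genes = 45, the 54-sample design, ω = 2π/24, φ = 0, and ε uniform on
[0, 50·i] for integer noise level i (sd ≈ 14.4·i). The one-sided noise is
taken at face value; its nonzero mean is harmless because every downstream
criterion (z-scoring, Pearson correlation) is offset-invariant, and a
zero-centered variant is available as a config switch. β = 450 is the
package's calibration of the unspecified signal amplitude: with it,
per-sample gene detection crosses the 50 % mark near i ≈ 17, nearly all
genes pass for i ≤ 6, and at i = 30 gene-level detection has collapsed while
the PAL remains circadian in ≥ 99.99 % of replicates — the qualitative
regime the method is designed to exhibit. Event probabilities over
replicates (default 1000; tests use 200 with binomial slack):

* gene event at fraction q: p = P(circadian fraction < q), significance
  1 − p, monotone in q by construction;
* PAL event: p = P(PAL not circadian);
* f_P significance curve: the median f_P per noise level is compared to
  random same-size gene sets from a pure-noise background matrix
  (1000 × 54 uniform noise; after z-scoring the null is scale-free, so one
  background serves every level).

All Monte-Carlo outputs are bit-reproducible: replicate streams are spawned
from a single `numpy` SeedSequence.

### What the simulator does and does not show

It emulates exactly the cosine-plus-uniform-noise model on the study grid:
a best case of perfectly coherent, equal-amplitude, equal-phase genes with
homoskedastic noise. Real arrays have probe effects, heteroskedastic and
correlated noise, partial pathway participation and phase dispersion, all
of which blunt the PAL's advantage. Passing the synthetic acceptance checks
therefore demonstrates correctness of the machinery and the *direction* of
the robustness claim, not effect sizes on real data.

## Pipeline, sizes, runtime

Stage order: map → PAL → f_P permutation filter (α = 0.05) → ANOVA
(α = 0.01) → replicate averaging → sign alignment → ensemble → δ-subset →
final clusters → centroid fits. Stage counts are logged and monotone
non-increasing. Output tables are plain TSV, re-readable by the package's
own readers; reruns with the same seed are byte-identical.

Problem sizes in the shipped tests and acceptance script are chosen so the
whole suite runs in a few minutes on one CPU: permutation nulls of 200–500
draws (10 000 remains the analysis default), 200-replicate Monte-Carlo
curves (1000 for the headline p-value in `scripts/acceptance.py`), and a
300-gene, 10-pathway end-to-end fixture.

## Known limitations

* Incomplete designs (missing replicates) are rejected rather than handled.
* The frequency band [0.24, 0.28] is applied verbatim; it brackets 2π/24
  asymmetrically.
* The δ-removal order is greedy, not provably minimal.
* The f_P null draws gene sets i.i.d. uniformly; gene-gene correlation
  structure in real matrices makes this null permissive for pathways that
  overlap large co-regulated modules.
* No multiple-testing correction across pathways.
* Higher-order singular components are exposed read-only on `PALResult`
  (`activity_components`, one row per component) for diagnostics but are
  never propagated into clustering.
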