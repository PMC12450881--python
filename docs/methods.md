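# Methods

This note documents the statistical models implemented in `germdiv`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Phenotypic diversity

The diversity of a trait over a germplasm collection is measured by the
Shannon–Weaver index H′ = −Σ pᵢ ln pᵢ in natural-log units (nats), with
0·ln 0 := 0. Qualitative (graded or categorical) traits use their observed
class frequencies directly. The natural log is the convention of the
germplasm-diversity literature: a trait split 96.5% / 3.5% scores 0.15
nats (log₂ would give 0.22).

Quantitative traits must be discretized first. `bin_quantitative` uses ten
classes with interior boundaries at mean + k·sd for
k = −2, −1.5, …, +2 (first and last class open). The analytic index of a
normal trait under this grid is 2.088 nats (integrating the normal density
over the ten classes), and the ceiling is ln 10 ≈ 2.303 — consistent with
the values slightly above 2 that well-spread quantitative germplasm traits
typically show. Diversity literature varies in its binning rules; this one
is fixed, documented, and tested against the analytic value. A constant
trait (sd = 0) is rejected rather than silently scored 0.

The coefficient of variation is CV = 100·sd/mean (sample sd, ddof = 1).
Correlations are pairwise-complete Pearson by default (Spearman by flag),
with graded qualitative traits entering as their integer codes; pairs with
fewer than three complete observations are flagged undefined rather than
estimated. Significance convention: p < 0.05 significant (\*), p < 0.01
highly significant (\*\*).

## PCA, comprehensive score, and selection

Traits are mean-imputed (missing cells) and z-scored; principal components
come from the eigendecomposition of the correlation matrix. Components
with eigenvalue > 1 are retained by default (Kaiser rule), overridable.
By default only quantitative traits enter; coded qualitative traits can be
folded in with a flag, since graded scores are ordinal and their Pearson
covariances are interpretable only approximately.

The comprehensive score of accession i is F_i = Σₖ wₖ·score_ik over the
retained components, with wₖ = explainedₖ / Σ retained explained. Higher F
means a better overall phenotype under the component weighting. F is
invariant to component sign conventions when loadings and scores flip
together.

Accession clustering uses Ward linkage on Euclidean distances over the
standardized traits — the standard choice for morphological matrices,
producing compact groups — cut at k clusters (default 5). Representative
selection draws per-cluster quotas proportional to cluster size
(largest-remainder rounding, minimum 1), takes accessions within each
cluster in descending F, then runs a repair pass: any qualitative class
present in the collection but absent from the selection forces in its
highest-F carrier, evicting the lowest-F selected accession whose removal
does not break class coverage. The selection is deterministic given input
order, always has the requested size, and provably covers every
qualitative class whenever coverage fits within the target size.

## SSR locus statistics

Markers are biallelic and codominant: each primer has two band slots, and
(1,0) → AA, (0,1) → BB, (1,1) → AB, (0,0) → missing. The codominant
reading is forced by the fact that observed heterozygosity is reported —
Ho is undefined under dominant scoring.

With genotype counts (n_AA, n_AB, n_BB) and n = their sum:

- p(A) = (2·n_AA + n_AB)/(2n), missing calls excluded;
- Na = number of alleles with p > 0; Ne = 1/Σpᵢ²; I = −Σpᵢ ln pᵢ;
- Ho = n_AB/n; Nei's gene diversity h = 1 − Σpᵢ²;
- He = 2n/(2n−1)·h, Levene's unbiased correction with the locus-specific
  n (the PopGene convention);
- PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein), maximal at 0.375 for a
  biallelic locus. A band-pattern variant (Botstein sum over genotype
  pattern frequencies) exists behind a flag for comparison with
  dominant-scoring conventions.

The identity Ne = 1/(1 − h) holds exactly and is exploited by the
self-consistency checks: a printed h determines the biallelic frequencies
up to labeling, p = (1 + √(1 − 2h))/2, hence Ne and I.

Between populations, Nei's (1972) standard genetic identity is
I_N = J_XY/√(J_X·J_Y) with J_XY = mean over loci of Σ xᵢyᵢ (and J_X, J_Y
analogous); the J terms are averaged over loci **before** forming the
ratio — this is the formulation under which the published distance
triangle is exactly the negative log of the published identity triangle.
D = −ln I_N is symmetric and nonnegative. Note that the arithmetic mean of
pairwise identities is not exp(−mean D); summary "mean identity" values
are consistent with the geometric mean (the identity implied by the mean
distance), which is what the consistency check asserts.

## Band distances and UPGMA

The default accession distance is Dice (Nei & Li) on band presences:
d = 1 − 2a/(2a + b + c), with a the shared presences and b, c the
presences private to each accession — the standard for fingerprint band
data. Simple matching ((b + c)/slots) is available. By default all band
slots are compared (a 0 is informative absence of a band); a flag excludes
the slots of non-amplifying primers pairwise instead, for data where
(0,0) should be read as missing rather than as a null homozygote.

UPGMA repeatedly merges the closest pair of clusters at height d/2 and
updates distances by the size-weighted arithmetic mean, so leaf-to-leaf
patristic distance reproduces the input exactly on ultrametric matrices
(and the tree recovers the generating merge heights). Ties take the
lexicographically smallest pair of cluster labels, making trees
reproducible regardless of input order. Cutting removes the k−1 highest
merges; groups are numbered in leaf order and nest as k grows. The
implementation is validated against an independently formulated reference
(cluster distances recomputed as plain averages of the original pairwise
distances) and against scipy's average-linkage cophenetic matrix.

Marker PCA column-centers the binary band matrix and eigendecomposes its
covariance; no scaling, since all columns share the 0/1 scale.

## Admixture model and ΔK

Population structure uses the admixture likelihood: individual i has
ancestry fractions q_i over K sources, source k has allele-A frequency
p_kl at locus l, and the allele-A dosage g_il ∈ {0, 1, 2} contributes
g·ln(Σₖ qᵢₖpₖₗ) + (2−g)·ln(Σₖ qᵢₖ(1−pₖₗ)). This is the same generative
model sampled by Bayesian structure software; here it is maximized by EM
from a seeded random start, giving deterministic point estimates at desk
scale. The EM updates attribute each observed allele fractionally to the
K sources; Q rows sum to 1 after every update, P is clamped to
[10⁻⁶, 1−10⁻⁶], and the log-likelihood is non-decreasing at every
iteration (asserted in the tests, with a 10⁻⁷ floating-point allowance).
Missing dosages contribute nothing to the likelihood; K = 1 reduces to
the closed-form binomial likelihood at pooled frequencies. Defaults:
max_iter 2000, tol 10⁻⁶ log-likelihood gain, 10 replicates with seeds
base + index.

Replicate fits are label-switched; comparisons permute Q columns by
Hungarian matching on column inner products. Model selection follows
Evanno: ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)) over per-K
replicate means, defined only at interior K with at least two replicates
and positive sd. On simulated 3-population data the scan peaks at K = 3.

## Fingerprints and molecular IDs

A fingerprint code concatenates the two band bits of each primer in a
fixed order; the standard 12-primer ID order yields 24-character strings.
Two characters per primer is forced by 12 primers → 24 characters.
Minimal discriminating primer sets use a greedy heuristic — repeatedly add
the primer splitting the most currently indistinguishable accession pairs,
ties by input order — because exact minimization is exponential; at test
scale the greedy answer is checked against the exhaustive minimum
(asserted within +1, the classical greedy set-cover-style bound in
practice). ID payloads are deterministic labeled text
(Name/Unicode/Source/Classification/Code) suitable for any QR encoder;
raster QR rendering is deliberately out of scope — the scannable content
is the payload.

## Synthetic data generator

The generator emulates the two unpublished study matrices.

**Phenotypes** (default: n = 1,582, 12 quantitative + 10 qualitative
traits): quantitative traits are multivariate normal with the published
per-trait means and sds (sd = mean·CV/100) and the published pairwise
correlations among the eight core agronomic/yield traits (assembled into
the nearest correlation matrix where needed); qualitative traits are
independent categorical draws at the published class frequencies. A
per-trait flag clips draws at zero for physically nonnegative quantities;
it is off by default because with CV ≈ 60% clipping visibly distorts the
very mean/CV targets the generator exists to reproduce (a clipped normal
at mean 32.15, sd 19.30 shifts the CV from 60 to ≈ 57).

**Genotypes** (default: n = 147 in six regional populations of sizes
14/30/10/25/63/5, 15 loci): divergence follows Balding–Nichols — each
population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) around the
ancestral p, with mean p and variance F·p(1−p), F = f_div = 0.15 by
default. The default ancestral frequencies are calibrated by inverting
the published per-locus gene diversities, so the synthetic panel spans
the published range (≈ 0.03–0.49) including the near-fixed loci; generic
configurations draw p ~ Uniform(0.1, 0.9) instead. Ancestry is one-hot by
default or Dirichlet(α) anchored to the home population when an admixture
concentration is set. Genotypes are drawn from the individual's mixture
frequency f with P(AB) = 2f(1−f)(1−F_is); the default F_is = 0.7 matches
the heterozygote deficit of a predominantly selfing crop (panel means
Ho ≈ 0.05 against h ≈ 0.16) while still allowing heterozygote-rich loci
at F_is = 0. The generator returns the true (Q, P) for closed-loop
recovery tests. All randomness descends from one seed via SeedSequence
spawning, so phenotypes and genotypes are independently reproducible.

**What the generator does not emulate.** Individuals are sampled
independently given their population, so multilocus genotypes carry no
linkage or pedigree structure. One consequence: at the published per-locus
diversities (11 of 15 loci nearly fixed), independent sampling necessarily
produces many identical 24-character fingerprints across 147 accessions
(per-pair collision probability ≈ 1.5%), whereas a real panel of named
varieties can be fully distinguishable. Passing fingerprint-distinctness
tests on generic higher-diversity configurations therefore says nothing
about distinctness on low-diversity real panels. Electrophoresis
artifacts, null alleles, genotyping error, and trait-by-genotype
correlation are likewise not modeled: phenotype and genotype tables are
generated independently, so cross-domain analyses (e.g. selecting on F
then genotyping the selection) exercise the interfaces, not a biological
signal.

## Numerical conventions

- Frequencies must sum to 1 within 10⁻⁹ (renormalized inside tolerance);
  negative frequencies are errors.
- Gene-diversity inversion is defined for h ∈ [0, 0.5] (the biallelic
  range) and returns the p ≥ q root.
- Report tables round to 4 decimals on output; internal computation is
  full precision.
- Missing data: NaN in trait matrices, the string `missing` in genotype
  calls, never encoded as 0; CSV I/O accepts empty cells or `NA` and
  writes `NA`.
- All stochastic functions take explicit seeds; identical seeds give
  byte-identical fixtures, fingerprints, Q matrices and Newick trees.
- Problem sizes in the test-suite are desk-scale by design (panels of
  40–147 accessions, 15–60 loci, K ≤ 5, ≤ 5 replicates), which keeps the
  full suite in seconds while leaving every statistical property
  assertable.

## Known limitations

- The binning rule behind quantitative diversity indices varies across
  the literature; ours is one documented convention, so absolute H′
  values for quantitative traits are comparable only within-package.
- PIC for multi-allelic loci, He with unknown per-locus sample sizes, and
  exact reproduction of any specific study's full-panel tables are out of
  reach without the raw matrices; the package instead verifies every
  internally recomputable relationship (Ne and I from h, D from I_N).
- The EM admixture fit is a point estimate; it reproduces grouping
  behavior, not posterior uncertainty, and with few loci the likelihood
  surface can be multimodal — hence replicate starts and best-of
  selection.
- Ward clustering and UPGMA group counts depend on distance choices that
  published studies often leave unstated; group memberships should be
  read as reproducible conventions, not recovered ground truth.
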