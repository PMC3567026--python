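# Methods

## Similarity matrix (ccm)

Pearson correlation of every gene pair, computed pairwise-complete over the
samples where both profiles are observed (pandas' C kernel does the heavy
lifting). A pair is *undefined* — stored as 0 so it can never seed an edge,
and counted in `n_missing_pairs` — when fewer than `min_obs` samples are
jointly observed or when either profile is constant over them. The
`min_obs` default is 30, a conventional floor for a stable Pearson estimate
on expression data; constant probes are a normal outcome of upstream
filtering, so zero variance is not an error. Whether missing values should
be handled pairwise or by whole-sample deletion was a genuinely open
choice; pairwise-complete was chosen because it preserves the most
information per pair and degrades gracefully as missingness grows.

The binary store keeps only the lower triangle (with diagonal) as
little-endian float32 behind a 9-byte header (`RMTB`, version 1, uint32 n),
with gene identifiers in a `<path>.genes` sidecar. For n genes that is
9 + 2n(n+1) bytes, ~50% of a full float32 dump and an order of magnitude
below a text table. `min_obs` and the undefined-pair count are
construction-time metadata and are not persisted.

## Threshold selection (rmm)

At each candidate threshold t (default scan: start 0.92, step 0.001) the
matrix is pruned — |r| < t zeroed, genes with no surviving partner dropped,
diagonal kept at 1. Thresholding uses the absolute correlation so negative
co-expression survives; edge weights keep their sign. The spectrum of the
pruned matrix is computed with LAPACK's symmetric eigensolver, sorted, and
deduplicated at an absolute tolerance of 1e-6 (sparse matrices have
massively degenerate spectra; an exact-equality rule would be numerically
meaningless). Unfolding fits a monotone cubic (PCHIP) spline through
(eigenvalue, rank) at `max(5, ceil(u/20))` evenly spaced rank anchors
(first and last always included) and maps every unique eigenvalue through
it; spacings are first differences. Anchor subsampling smooths the rank
staircase into an estimate of the integrated eigenvalue density, and u/20
keeps anchor density scale-free. A monotone spline is used deliberately:
an interpolating natural cubic can overshoot between anchors and produce
negative spacings, which are meaningless for an NNSD. Interpolating the
endpoint ranks fixes the mean spacing at exactly 1. On a 500 × 500 GOE
matrix this unfolding reproduces the Wigner surmise to a Kolmogorov
distance of ~0.025.

The NNSD is binned into 60 equal bins on [0, 3] (spacings beyond 3
discarded) and compared to the unit-mean exponential renormalized over
[0, 3], so expected and observed totals match and the statistic has
df = 59. χ² = 100 at df 59 corresponds to an upper-tail p of ~7e-4 — the
p ≈ 0.001 significance convention. Fewer than 120 unique eigenvalues (two
spacings per bin) gives an undefined χ² for that level; with 120–599 the
statistic is computed but flagged unstable via a warning.

Scan logic: the *divergence* threshold is the highest t whose χ² reaches
the significance level (100) and stays at or above it through every lower
level until some level reaches the confirmation value (200). A drop back
below 100 marks the earlier rise as a local maximum and resets the
candidate; this continuous-rise reading is the stricter of the two possible
interpretations of "confirm at 200" and is what the local-maximum rationale
implies. One unfolding is performed per level (no averaging across spline
parameterizations). On confirmation the reported network threshold is
`divergence + step` — the last level whose spectrum was still Poisson; the
network must be cut on the noise-free side of the transition. If the scan
reaches the floor `t_min` unconfirmed it raises, carrying the full trace; a
trace whose every computable χ² already exceeded 100 is flagged as
*homogeneous* (correlations high across most of the matrix — no Poisson
regime exists, and no threshold can be found).

`t_min` defaults to 0.5 to bound routine runtimes, and is an explicit
parameter because where the transition falls is a property of the data:
with 100 samples the sampling noise floor of Pearson r sits near
2–4 standard errors ≈ 0.3–0.45, so the planted-module validation scans to
0.2. Levels at which no new matrix entry crossed the threshold reuse the
previous level's χ² (the pruned matrix is unchanged), which keeps fine
steps cheap.

## Topology metrics

Average degree is 2E/N. The clustering coefficient is the average local
(Watts–Strogatz) form with degree-<2 nodes contributing 0 — the dominant
convention in the co-expression literature (the alternative, global
transitivity, was the other candidate; one had to be picked and the choice
is documented here). The scale-free exponent γ is the continuous
maximum-likelihood estimate γ̂ = 1 + n·[Σ ln(k_i/(k_min − 0.5))]^−1 over
degrees ≥ k_min: deterministic, dependency-free, and validated by parameter
recovery (γ = 1.5 recovered to within 0.05–0.1 at n = 10⁴; the estimator
carries a small negative bias at k_min = 1 from the continuous
approximation to a discrete law). It requires at least 10 qualifying
degrees and errors when all degrees equal k_min, where the exponent is
unidentifiable.

## Link communities

Edges incident on a common node k, (i, k) and (j, k), are scored with the
Jaccard similarity of inclusive neighborhoods n⁺(i), n⁺(j); non-adjacent
pairs have similarity 0, and weights are ignored (the method is
topological). Single-linkage clustering of edges under distance 1 − J gives
a dendrogram, cut at the level maximizing partition density D; ties prefer
the higher-similarity (finer) cut, making the result deterministic given
the canonical lexicographic edge order. The degenerate cut at distance 1 —
which would coalesce non-adjacent edges — is excluded; it does not
correspond to any similarity level. Communities of n_c = 2 nodes (single
edges) contribute 0 to D and are excluded from *module counts* (default
minimum 3 nodes, configurable), since a lone edge has no enrichable
structure.

## Enrichment and functional similarity

Annotations are a flat gene → term table from any vocabulary; no ontology
propagation. Enrichment of a term in a module is the upper-tail
hypergeometric probability with the background taken as the annotated genes
of the network under test — a network-relative background keeps the
global-versus-perturbed comparison fair. Raw p ≤ 0.001 is retained with no
multiple-testing correction, matching the protocol this package implements.

Functional similarity of two networks: each module with ≥ 1 enriched term
becomes a binary incidence vector over the union of terms enriched in
either network (term-incidence, not gene-membership, is the compared
object — it is what the enrichment stage defines); every perturbed module
is matched to the reference module maximizing Cohen's κ, and the mean of
the maxima is the score. Best-match-then-mean is the only pairing under
which identical module sets score 1; a mean over all pairs is driven to 0
by the off-matches regardless of similarity. κ = 0.6 is quoted as the
conventional cutoff for a meaningful match.

## Perturbation harness

For each grid cell (sample_fraction, probe_fraction) and replicate r, a
uniform subset of ⌈round⌉(fraction × count) samples and probes (independent
draws, minimum 1, original order preserved) is taken with seed
`base_seed + r`, and the entire pipeline is re-run with unchanged
parameters. Subsets are drawn fresh per replicate rather than nested.
Replicates whose scan fails to confirm are recorded as failed, never
silently reseeded — retrying would bias the robustness statistics toward
easy draws. Reported per replicate: threshold, node/edge counts, ⟨k⟩, C, γ,
shared nodes/edges versus the global network, edges lost
(= E_global − shared) and new (= E_perturbed − shared), module count, and
average κ; aggregates are per-cell means and standard deviations.

## Synthetic data

Each planted module m has an independent standard-normal latent factor
f_m over samples; a module gene's profile is
`noise_sd · (loading·f_m + √(1−loading²)·ε)` with ε i.i.d. standard normal,
and background genes are pure noise. Expected within-module correlation is
exactly loading² (default loading 0.92 → r ≈ 0.846, the strong-co-expression
regime RMT thresholding targets) and 0 elsewhere, giving closed-form
oracles; the single-factor construction is positive definite at any size.
Defaults — 600 genes, 100 samples, 5 modules × 20 genes, unit noise —
are the validation conditions used throughout the test suite and the
acceptance script. All randomness flows from one seed through spawned
streams per purpose, so fixtures are bit-reproducible. The annotation
fixture gives every module gene its module's distinctive terms plus one
broad term drawn uniformly over all genes, so the background universe
covers the full gene set and broad terms are never module-enriched.

What the generator does *not* emulate: platform artifacts (probe
saturation, batch effects, normalization quirks), correlated background
structure, heavy-tailed expression distributions, or overlapping/nested
modules. Passing the planted-truth suite therefore shows the pipeline's
correctness and its behavior under sampling noise, not its performance on
the full messiness of public repository data, where thresholds land much
higher (the noise floor of thousands of heterogeneous samples is far
lower than that of 100 homogeneous synthetic samples).

## Problem sizes and determinism

The validation suite runs the full pipeline at 600 genes × 100 samples
(eigendecompositions up to 600 × 600 across a ~700-level scan complete in
under a second thanks to the unchanged-level cache), and the perturbation
trend uses 5 base datasets × 10 replicates per cell at a scan step of
0.002. These sizes were chosen to make every validation a from-scratch
computation while keeping a complete run interactive. Every stochastic
component takes an explicit seed; repeated runs are bit-identical.

## Known limitations

- The χ² confirmation requirement (continuous rise from 100 to 200) can
  narrowly fail on individual datasets whose statistic peaks just below
  200 on its first rise through the transition; the scan then confirms
  deeper in the noise regime with correspondingly more noise edges. Finer
  steps and larger matrices shrink the effect.
- Spearman/Kendall/mutual-information similarity, ontology-aware
  enrichment, weighted link clustering, and global-transitivity clustering
  are out of scope.
- `read_similarity_binary` reconstructs values at float32 precision; the
  float64 matrix in memory round-trips exactly only if it was float32
  representable.
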