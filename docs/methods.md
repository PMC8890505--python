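# Methods

This note documents the statistical machinery in `sdmnet`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Contest statistics

**Dyad summaries.** A dyad's latency is the time of its first aggressive
act (antiparallel display, circle, bite, chase or strike) from recording
start; a dyad with no aggressive act has missing latency and is excluded
from latency comparisons. Per-behavior frequencies are totals divided by
resolution time (per minute), and the aggressive/submissive aggregates sum
the five aggressive and three submissive (freeze, flee, retreat) behavior
frequencies respectively.

**Normality-gated two-group test.** Both samples are screened with
Shapiro–Wilk at a gate alpha of 0.05 (a convention; the gate level is a
parameter). If both pass, a two-sided two-sample t-test; otherwise a
two-sided Mann–Whitney test. A constant sample, for which the Shapiro–Wilk
statistic is undefined, fails the gate by definition. The Mann–Whitney
statistic is reported in the rank-sum convention
W = U + n₁(n₁+1)/2 — the sum of the first sample's pooled ranks — with the
U↔W conversion in the implementation; scipy's exact method is used for
small tie-free samples and the normal approximation otherwise.

**PCA of display totals.** Totals are square-root transformed (variance
stabilization for counts), column-centered, and the sample covariance
matrix (ddof = 1) is eigen-decomposed. Covariance (unscaled) PCA is the
default because display totals share a common count scale;
correlation-matrix PCA is available via `scale=True`. Zero-variance
directions report zero proportion of variance. The sign of each component
is fixed so that its largest-magnitude loading is positive (first such
variable on ties); components are otherwise defined only up to sign.

**perMANOVA.** Euclidean distances on the (square-root transformed)
behavior totals. With n observations in a groups, the partition is
SS_total = Σ_{i<j} d²ᵢⱼ / n and SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g,
and the pseudo-F is (SS_between/(a−1)) / (SS_within/(n−a)). The reference
distribution permutes raw group labels over individuals (the vegan-style
default, not residual permutation). The Monte-Carlo p-value uses the
add-one correction p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is never 0 and
has resolution 1/(n_perm+1); 999 permutations is the default. An
`exhaustive=True` mode enumerates every distinct label assignment and
reports the exact fraction with F* ≥ F (the observed assignment counts, so
p > 0); it is feasible only for tiny samples and is the oracle mode used
in the tests. Completely degenerate data (all observations identical)
report F = 0, p = 1. Groups of size 1 are rejected because the
within-group term of the partition is undefined for them.

## Regional activation tests

Within one sex, each region is tested across the three social conditions
with the tie-corrected Kruskal–Wallis H (all-equal counts are guarded to
H = 0, p = 1). Raw p-values are Benjamini–Hochberg adjusted across the 19
regions *within sex* (19 tests; testing across both sexes at once is a
caller choice — run on the concatenated table). Regions passing q ≤ 0.05
receive Dunn's rank-based pairwise comparisons (normal approximation on
mean-rank differences with tie correction), BH-adjusted over the three
condition pairs within each region. Dunn's procedure is implemented here
directly since no installed library provides it.

A power limit worth knowing: with 5 fish per condition, even a fully
separated group yields a chi-square Kruskal–Wallis p of about 0.008, which
cannot survive BH over 19 regions; at 8 fish per condition a 10-sigma
shift is detected after FDR essentially always. Group sizes of 6–9 per
stratum are typical for this assay and sit at the edge of that regime.

## Bootstrapped connectivity networks

For one sex × condition stratum with n fish:

- **Subsamples.** All C(n, s) subsamples of size s = 7 by default. Because
  strata of 6–7 fish admit no (or only one) such subsample, n ≤ s falls
  back to s_eff = n − 1 (leave-one-out, guaranteeing n instances); a
  `strict_s` flag errors instead. A `random_m` policy draws m distinct
  seeded subsamples for large strata, where full enumeration is
  impractical.
- **Instance networks.** Pearson correlation by default (Spearman
  available) across the subsample's fish; a zero-variance region's
  correlations are set to 0 rather than NaN-propagated, excluding it from
  retention. Exactly k = round(ρ·E) edges with the largest |r| are kept
  (ρ = 0.23, E = 171 pairs of 19 regions, hence k = 39); ties at the
  cutoff break by lexicographic (i, j) index order; `floor`/`ceil`
  rounding are available.
- **Aggregation.** Element-wise mean over instances with non-retained
  edges contributing 0 (default) — this shrinks edges that are unstable
  across subsamples toward zero, which is the point of density
  thresholding; `mean_over_retaining` (average only over instances that
  kept the edge) is available.
- **Sign split.** The aggregated network's positive edges form the
  excitation subnetwork, negative edges the inhibition subnetwork;
  zero-weight edges belong to neither.
- **Robustness.** `robustness_rank_correlation` reports the Spearman
  correlation of aggregated edge weights between runs at s and s+1, as a
  check that conclusions do not hinge on the subsample size.

## Edge-weight comparisons and balance

Comparisons operate on the nonzero aggregated edge weights of treatment
networks (up to 171 per network). Each contrast reports the two-sided
two-sample Kolmogorov–Smirnov D (distribution shape), the two-sided
Mann–Whitney U (location), and Cohen's d with pooled SD (first sample
minus second); |d| bands at 0.2/0.5/0.8 label effects
negligible/small/intermediate/large (configurable). The balance analysis
compares a treatment's excitation weights against the *absolute values* of
its inhibition weights — magnitudes, because comparing signed values would
separate the samples trivially — so d > 0 means excitation dominates. A
treatment with an empty excitation or inhibition side is flagged
`one-sided network` and not tested. Edges sharing a node are not
independent samples; the tests treat them as i.i.d., which matches common
practice for this analysis style, and a permutation-of-individuals
alternative is a possible extension, not implemented here.

## Eigencentrality hubs

Node scores are the leading eigenvector of the absolute-weight matrix
(non-negative by Perron–Frobenius), computed by power iteration with a
deterministic uniform start vector, tolerance 1e-10 and at most 10,000
iterations — reproducible without a seed, and verified against dense
eigendecomposition in the tests. If the nonzero-edge graph is
disconnected, the component with the largest leading eigenvalue is scored
and all other regions get 0. Scores are normalized to unit Euclidean norm;
ranking ties break lexicographically by region name. Hubs are the top
k = 8 regions (configurable); cross-sex hub intersections return
(shared, only-a, only-b) partitions of the two top-k sets. Region labels
with anterior/posterior suffixes are accepted as synonyms of the
rostral/caudal canonical names (e.g. `Vv_a` ≡ `Vv_r`) via
`sdmnet.canonical_region`.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture.

**Contests.** Per-behavior totals per fish are negative binomial with mean
rate × resolution time and dispersion k = 5 (variance m + m²/k). Default
rates encode the qualitative sex asymmetry of zebrafish contests — males
bite/strike/retreat more, females use antiparallel displays more — with
absolute scales (0.4–2 events/min) chosen as plausible conventions.
Latency and contest duration are log-normal (positive, right-skewed);
median latency 2 min for both sexes, median duration 15 min (males) vs
9 min (females), encoding faster female resolution. Resolution time is
latency + duration, so it always exceeds the latency. The opponent with
more aggressive acts at resolution wins; ties flip a coin from the dyad's
own RNG stream. Event times are uniform between first attack and
resolution, with the earliest aggressive act anchored exactly at the
latency so summaries recover it. Each dyad has an independent child RNG
stream derived from (seed, sex, dyad index), making outputs bit-stable and
insensitive to how many dyads precede a given one.

**Activation tables.** Counts are negative binomial (default mean 40,
dispersion 8) per region, with correlation structure imposed by a Gaussian
copula: latent multivariate normal with the target correlation matrix,
mapped through Φ and the NB quantile function. Planted structure comes as
equicorrelated blocks (any target r; an equicorrelated block of size m is
positive semi-definite only for r ≥ −1/(m−1), so strong negative structure
is planted as pairs) and one-factor hubs (corr(hub, spoke) = strength,
corr(spoke, spoke) = strength², PSD by construction). The implied matrix
is validated PSD at model construction, naming the offending block. Group
sizes default to 8 fish per sex × condition, inside the 6–9 range typical
of this assay.

The copula transfers the latent correlation to the count scale with mild
attenuation (a latent 0.9 yields empirical count correlations of roughly
0.85–0.9), which the recovery tolerances account for.

**What the synthetic validation shows — and does not.** Passing recovery
tests demonstrates that the pipeline's estimator chain (subsample
correlations → density thresholding → averaging → sign split → centrality)
faithfully recovers structure that is present and strong. Structure
recovery is quantified at n = 500 individuals per stratum — the scale at
which the generator's planted correlations are themselves recoverable —
using seeded random subsamples of size s = 7. At the 6–9 fish per stratum
of a real assay, the sampling noise of 171 correlations estimated from
7–8 fish produces spurious |r| ≈ 0.9 pairs often enough that the top-edge
precision for planted r = 0.9 blocks drops to roughly 0.8: at that scale
individual edges of a single aggregated network should be read as
descriptive, with confidence coming from the distribution-level contrasts
and from robustness checks rather than from any single edge. The generator
also does not emulate real anatomical covariance (smoothly decaying
correlations between neighboring nuclei), inter-individual baseline
heterogeneity, or scoring noise in the ethogram.

## Pipeline

`run_pipeline` executes data → ethogram → activation → networks →
netstats → centrality from a single YAML config, writing tidy CSVs and a
`manifest.json` carrying the package and library versions, the global seed
and a config hash (the hash covers the analysis parameters, not the output
directory). The global seed propagates to every stochastic stage
(generators, permutations, random subsampling); reruns with the same
config are bit-identical apart from manifest timestamps, and stages whose
outputs already exist under the same config hash are skipped. perMANOVA in
the pipeline uses sqrt-transformed display totals (matching the PCA
transform); frequencies can be analyzed by calling the library directly.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and the
acceptance script in under two: type-I calibration uses 500 null
perMANOVA simulations (199 permutations, 2 × 8 observations) and 1000
gated-test simulations (n = 30 per group); recovery rates use 100 seeds
(precision, hub) and 200 runs (balance sign) at 50 random subsamples per
network. These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands (e.g. ±0.01 on a 0.05 rejection rate at 500
simulations).
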