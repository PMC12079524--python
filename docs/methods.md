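# Methods

This note documents the models and estimators implemented in `coexmod`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Robust correlation

Gene–gene similarity is the biweight midcorrelation (bicor). For a vector
`x`: `u_i = (x_i − med(x)) / (9·mad(x))`, weights
`w_i = (1 − u_i²)²·1[|u_i| < 1]`, transformed values
`x̃_i = (x_i − med(x))·w_i`, and
`bicor(x, y) = Σ x̃ỹ / √(Σ x̃² · Σ ỹ²)`. The `9·mad` denominator uses the
raw median absolute deviation with **no** 1.4826 consistency constant —
that is the canonical definition of the estimator. A vector with zero MAD
falls back to Pearson centering (logged). The refinement that caps the
proportion of down-weighted observations is not implemented.

Missing values are handled pairwise-complete: per-gene transforms are
computed on each gene's observed entries and pair sums run over the
common support; pairs with fewer than `min_pairs` (default 3) complete
observations are set missing and become adjacency 0. Rows with more than
20% missing values are dropped at load (configurable). P-values use the
asymptotic transform `t = r·√((n−2)/(1−r²))` with pairwise `n`.

Pearson and Spearman are available through the same interface; bicor is
the default everywhere because single 6-SD array artifacts shift a
Pearson coefficient at n = 40 by ≈ 0.2 while bicor moves by < 0.05 (this
contrast is an asserted test, not an aspiration).

## Network, scale-free fit, TOM

Unsigned adjacency `a_ij = |b_ij|^β` (default) or signed
`((1+b_ij)/2)^β`. Unsigned is the default because the analysis targets a
driver gene with strong *negative* module correlations, and an unsigned
network keeps anti-correlated partners in the same neighborhood; signed
is a config switch. β defaults to 8; `pick_soft_threshold` reports the
scale-free fit over a candidate ladder and returns the smallest β with a
valid fit above the target (default 0.8), falling back to the best fit
with a warning. The fit bins connectivity into 10 equal-width bins,
regresses `log10(mean frequency)` on `log10(mean k)` over non-empty
bins, and is flagged invalid when the slope is non-negative.

Topological overlap: `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
with `ℓ_ij = Σ_{u≠i,j} a_iu·a_uj`, unit diagonal, zero by convention for
isolated pairs. Clustering uses `1 − TOM` with average linkage (scipy);
tie-breaks between exactly equal merge heights follow scipy's
deterministic agglomeration order.

## Dynamic hybrid tree cut

The cut has two stages, controlled by `CutParams` (deep split 0–4,
minimum module size, merge threshold, PAM stage, static cut height
defaulting to 0.99 of the maximum merge height).

Stage 1 cuts the dendrogram statically, then decomposes each component
into branches. A merge is a split point when both sides hold at least
`min_module_size` leaves and the *gap* — the joining height minus the
looser side's core scatter (its mean internal pairwise dissimilarity) —
reaches a deep-split-dependent minimum. Measuring the gap against core
scatter rather than the child's top merge height is deliberate: absorbed
straggler genes raise a branch's top height and would otherwise blur
genuine between-module separations. The deep-split mapping uses five
documented constant pairs (max core scatter 0.64 … 0.95, min gap
`0.75·(1 − scatter)`), expressed as fractions of the range between the
5th-percentile merge height and the cut height; the constants live in one
table (`module_detect.DEEP_SPLIT_*`) for recalibration. A branch becomes
a module when it meets the size floor and its core scatter is within the
deep-split bound; a too-loose branch is force-split at its top merge and
its pieces re-examined, so loose agglomerates cannot masquerade as
modules. Everything else is unassigned (label 0, "grey").

Stage 2 (PAM, default on) lets each unassigned gene join the module with
the smallest average dissimilarity to members, provided that average is
below the gene's average dissimilarity to non-members. By default a gene
may only join modules within its own static-cut branch of the dendrogram
(`pam_respects_dendro`, mirroring the canonical hybrid cut's default).
Without that constraint, pure-noise genes are systematically absorbed on
TOM dissimilarity — a noise gene's overlap with a module is always
slightly higher than with other noise — which empirically destroys the
partition; the unconstrained rule remains available as a switch.

Modules whose eigengenes satisfy `1 − cor(ME_a, ME_b) < h` are merged
iteratively, closest pair first, recomputing eigengenes after each merge
(default `h = 0.15`). Labels are reassigned contiguously by descending
size and mapped to the conventional color ladder (turquoise, blue,
brown, …); grey is always label 0 and is excluded from every downstream
inference.

The hyperparameter sweep re-runs cut+merge over a grid (default: deep
split {2, 3} × min size {20, 30} × merge threshold {0.1, 0.25} × PAM
{on, off}) and reports module counts/sizes and all pairwise adjusted Rand
indices, with unassigned treated as its own class.

## Eigengenes, hubs, module–trait

A module eigengene is the first right singular vector of the module's
row-standardized expression, scaled to unit variance (ddof = 1) and
oriented so the mean member correlation is non-negative; `pve` is the
first squared singular value over the total. Constant member rows are
dropped with a warning. `kIM` is the within-module adjacency row sum
(diagonal excluded); `kME` the correlation with the own-module eigengene;
hub rank orders by descending `kIM`, ties by descending `kME` then gene
ID. Module–trait association is plain Pearson correlation of eigengenes
with trait columns over a stated sample subset, with asymptotic p.

## Module preservation

Seven statistics per module on the ref/test gene overlap (≥ 3 genes and
≥ 50% of the module required): test-data density (mean intramodule
correlation, mean adjacency, eigengene pve, mean |kME|) and cross-dataset
pattern (correlation of kIM vectors, of kME vectors, and of the
vectorized intramodule correlation entries). Estimator choices that
matter: kME is computed with the network's robust transform (a single
contaminated cell otherwise wrecks a gene's kME in one dataset only),
and the two connectivity-vector comparisons use Spearman rank
correlation, because the soft-threshold power raises sampling noise to
the 8th power and the resulting heavy tails overwhelm a product-moment
correlation.

The null draws, per permutation and module, a random gene set of the
module's size without replacement from the genes shared by both datasets;
all seven statistics are evaluated on the same draw. One-sided add-one
`p = (1 + #{null ≥ obs})/(P + 1)` (floor `1/(P+1)`), `Z = (obs −
mean_null)/sd_null` (missing when the null sd is 0), and
`Zsummary = median(median(Z_density), median(Z_pattern))`. A module is
"significantly preserved" when all seven p are below 0.05. Default
`n_perm = 200` puts the permutation CI near ±0.03 at p = 0.05.

A caveat the tests make explicit: the pattern statistics measure whether
a module's *internal gradient* replicates, so they are only informative
for modules with genuine core–periphery structure; for a homogeneous
module their population value is ≈ 0 while random null sets inherit
reproducible structure from their module-gene contamination. Verdict
fractions are therefore evaluated on cohorts generated with strong
membership heterogeneity (see the generator below).

## Differential co-expression

Per module, `D = mean |cor^A_ij − cor^B_ij|` over member pairs between
the two condition subsets, and per gene `d_i` the row mean of the same
differences. The null permutes condition labels — within donor pairs
(label swap per pair) when a pair ID is supplied, freely otherwise — with
add-one p; a module is "preserved across conditions" when its p exceeds
0.05. Both the preservation test and this one are provided because a
condition-level replication claim can rest on either construction.

## Signature scores and prioritization

The per-sample signature score ranks all G genes within a sample
(ascending, ties averaged), normalizes ranks to [0, 1], averages over the
S present signature genes, and min–max standardizes by the attainable
extremes `(S−1)/(2(G−1))` and its complement, so top/bottom placement
scores exactly 1/0. Only within-sample ranks enter, making the score
bitwise invariant (tested at 12 decimals) under any strictly increasing
per-sample transform — the operational meaning of robustness to
between-sample and between-platform differences. Validation correlates
each module's top-k hub score (default k = 120) with a reference
signature score across an independent cohort.

Candidate ranking inside the chosen module (default: strongest |R|
module of the screen's sign against the driver trait): each gene's
correlation with the driver is computed with the network's robust
correlation (Pearson switchable) over all samples by default; eligibility
requires the configured sign and raw p < alpha (default 0.05; BH q
reported alongside). Eligible genes are ordered by an equally weighted
mean of fractional hub rank and fractional |r| rank (weights
configurable, documented as a reconstruction), the top N (default 47)
flagged, ineligible genes listed below with reasons, and the driver
excluded from its own module. Paired differential expression is the
classical paired t on per-pair log2 differences, with explicit degenerate
handling (all-zero differences: t = 0, p = 1; constant nonzero: t = ±∞
flagged). Over-representation is the upper-tail hypergeometric against
universe-restricted gene sets with BH adjustment across sets.

## Synthetic cohorts

A Gaussian latent-factor model. A latent driver factor `D ~ N(0,1)`
anchors the construction: a module with target driver correlation `c`
receives eigengene `e_q = c·D + √(1−c²)·ξ_q`, so `cor(D, e_q) = c`
exactly in population for any |c| ≤ 1, and eigengenes of driver-linked
modules are mutually correlated (`c_q·c_q'`) — as real module summaries
are. The driver gene itself observes `D`. Members load
`x_i = √ρ_i·e_q + √(1−ρ_i)·ε_i`, so `cor(x_i, e_q) = √ρ_i` in
population; background genes are pure noise. Every planted quantity maps
to a closed-form target, which is what makes parameter-recovery testing
possible.

Defaults (the study-scale conditions): 2000 genes — five modules of
200/150/100/60/40 members plus background — and 40 samples in 20
case/control pairs; driver plan (+0.90, −0.70, +0.66) on modules 1–3.
Per-member strengths are heterogeneous, `ρ_i ~ U(ρ−0.15, ρ+0.05)`,
giving modules genuine hubs and a decaying connectivity spectrum (the
scale-free fit of the resulting network exceeds 0.8). Module-level ρ
defaults rise as modules shrink (0.72/0.70/0.75/0.78/0.80): at soft
power 8 and 40 samples the TOM dissimilarity of a 40-gene module with
ρ ≤ 0.6 sits above the 0.99 static cut height, i.e. below the
detectability floor of the fixed-β design, and plaque co-expression
modules of that size are reported as tight; the preservation
monotonicity tests still exercise ρ from 0 to 0.9 explicitly.

The candidate gene is a hub of the −0.70 module (ρ = 0.90) whose driver
correlation equals the module's own (−0.70): in a latent-factor module,
hubness and driver correlation are coupled (`√ρ_i·c`), so a "top hub
that stands out on both axes" is exactly a coupling-consistent strong
hub; it carries a +0.5 log2 case shift. The paired design adds a shared
per-pair random effect (sd 0.3) and the condition shift to the candidate
and its module only. Outlier contamination replaces 1% of cells with
values 6 row-SDs from the row mean; the driver gene row is left
uncontaminated because it serves as the continuous trait anchor whose
module correlations are screened with plain Pearson — contaminating it
would test trait hygiene, not network robustness. A validation cohort
reuses the base cohort's memberships and per-member ρ with fresh
samples, optionally distorted per gene in location/scale (the rationale
for rank-based scoring); `collapse_in_cases` can decohere chosen modules
in the case condition to exercise differential co-expression power.

What the generator does **not** emulate: array-specific artifacts (batch
structure, probe saturation, background correction), count noise,
correlated background genes, modules sharing genes, or within-pair
correlation of module activity (each sample draws its own factor
values — one consequence is that a +0.5 log2 shift at 20 pairs is only
marginally significant in the paired test, so differential-expression
p-values on synthetic cohorts are reported, not asserted). Passing tests
therefore demonstrate the estimators' correctness and calibration under
a clean factor model with heavy-tailed contamination, not performance
under platform pathologies.

## Determinism and numerics

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); no global state. Reports are reproducible
byte-for-byte under a fixed seed. Tables are tab-delimited UTF-8 with
10-significant-digit floats, which round-trips the synthetic data
exactly at the precision the pipeline consumes. Correlations are clipped
to [−1, 1]; TOM to [0, 1]; degenerate denominators (constant vectors,
isolated pairs, zero-sd nulls) resolve to documented conventions with
stable warning codes rather than NaN propagation. Problem sizes used in
the test suite (e.g. 1000-gene single-module cohorts for permutation
calibration, 50-seed averages for correlation recovery) were chosen to
give each statistical check comfortable margins at desk scale while the
full suite stays fast.

## Known limitations

- No block-wise network construction: matrices are dense, so ≳ 30k genes
  will strain memory.
- The dynamic hybrid cut is a faithful re-derivation, not a numerical
  clone of the reference implementation; partitions can differ in
  borderline branches.
- The identity of the seven preservation statistics follows the standard
  module-preservation literature but is a declared reconstruction; the
  set is switchable without code change.
- The candidate composite (hub rank ⊕ |r| rank, equal weights) is a
  documented reconstruction of an under-specified ranking; weights are
  configurable.
- GEO series-matrix parsing covers the common single-table dialect only;
  probe collapse assumes a probe maps to at most one gene.
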