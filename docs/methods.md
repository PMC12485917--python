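# Methods

This note records the models, estimators, numerical conventions and design
choices behind `hicstats`, at the level of detail a user needs to judge what
a passing test suite does — and does not — establish.

## Coordinates and data model

All coordinates are 0-based, half-open, in bp. A genome is tiled into
fixed-size bins (the last bin of a chromosome may be short); distances are
measured between bin midpoints. A contact matrix is dense, symmetric and
nonnegative, with a per-bin validity mask and per-bin balancing weights;
masked bins are excluded from every statistic but never deleted from
storage, so `total_contacts` is invariant under masking. Desk-scale genomes
(the bundled 8 × 30–60 Mb test genome with a 16.6 kb mitochondrial contig,
and a 1/5-scale 22-autosome human-proportioned genome) keep dense matrices
in the hundreds of MB at 100–250 kb bins.

## Hygiene: masking and balancing

`mask_low_coverage` masks bins whose marginal is zero or whose
log₁₀-marginal falls more than `mad_k` (default 5) median absolute
deviations below the median. The MAD is floored at 0.1 log₁₀ units:
synthetic maps are far more uniform than real libraries, and without the
floor the MAD collapses to sampling noise and the filter swallows ordinary
coverage variation (chromosome ends, compartment identity) instead of the
order-of-magnitude dropouts it is meant for. Marginals and reference
statistics come from the stored counts, making the operation exactly
idempotent.

`ic_balance` is symmetric iterative correction (Sinkhorn): weights are
updated by the square root of the marginal ratio until the relative spread
(max − min)/mean of balanced marginals falls below `tol` (default 1e-5,
diagonal included, max 200 iterations); weights are scaled so the mean
balanced marginal is 1. Non-convergence raises a warning and is recorded on
the result — some zero-pattern matrices balance only asymptotically.

### A recurring finite-size artifact, and its correction

Balancing equalizes each bin's *total* marginal. On a finite chromosome
with power-law decay, end bins are missing close neighbors, so balancing
hands them systematically larger weights; the residual appears as a
positional (per-bin multiplicative) factor wherever balanced values are
compared across positions. Three estimators correct for it explicitly,
each time by dividing pairs by the product of per-bin factors estimated
from observed/expected row means:

* **insulation** — factors from the ratio of observed to expected cis row
  sums (count-weighted, hence essentially noise-free); otherwise the
  insulation profile bows over tens of Mb and the bow's interior minimum
  masquerades as a strong boundary;
* **compartment eigenvectors** — O/E rows are divided by their row-mean
  outer product before the correlation step; otherwise neutral bins inherit
  the per-bin weight pattern, which correlates with compartment labels
  whenever c_AA ≠ c_BB and pushes neutral bins out of the ambiguous band;
* **territory statistics** — trans pairs are divided by per-bin factors
  estimated against *unflagged* partners only, so genuine telomere or
  centromere clustering does not feed back into its own correction. On
  noise-free maps with planted w_tel = 3 the telomere–telomere enrichment
  reads 3.0; without the flag-aware restriction it would be damped.

## Distance decay

`ps_curve` pools balanced cis pairs across chromosomes into log-spaced
distance bins (10 per decade by default) and normalizes the curve to unit
area in log₁₀(s), so cross-sample comparisons are shape-only — the raw
level of a balanced map is arbitrary. The derivative is a centered finite
difference of the 5-point moving average of log₁₀P against log₁₀s, reported
at bin centers. Slopes are fitted by least squares over 0.1–10 Mb; on
noise-free generator matrices the fit recovers the planted exponent within
±0.05 (the short-distance end wiggles where few discrete bin offsets fall
into each log bin — an artifact of 250 kb resolution, not of the data).

`cis_fraction` is a raw-count statistic (fractions of reads are counts, not
balanced quantities): 100 × same-chromosome counts / all counts, diagonal
self-pairs included, mitochondrial contig excluded from both numerator and
denominator.

## Compartments

Per chromosome: balanced cis map → per-diagonal O/E → per-bin factor
correction (above) → Pearson correlation matrix → eigendecomposition.
Because the largest eigenvector does not always track compartments, the
candidate is chosen among the top three eigenvalues by absolute correlation
with a reference track (GC-like proxy on real data; the planted track in
simulations), and sign-oriented so that correlation is positive; if no
candidate reaches |r| = 0.1 the leading eigenvector is used and a warning
raised. Chromosomes with fewer than 20 unmasked bins are left undefined.

The reported per-bin value is the **profile correlation score**: the
Pearson correlation between the bin's corrected O/E profile and the
selected eigenvector pattern. Unlike raw eigenvector loadings, whose scale
is an arbitrary normalization choice, this score is bounded in [−1, 1] and
depth-stable: bins participating in the checkerboard score near ±1 at any
reasonable depth, while bins with no consistent compartment preference
score near zero (noise floor ~ n_bins^(−1/2)). The A/B call thresholds
(A > +0.05, B < −0.05, the published convention) therefore separate signal
from neutrality without per-sample tuning. Calls on bins with no value are
"undefined" and excluded from all denominators.

Saddle analysis sorts A/B-called bins by EV1 into 50 quantiles (ties broken
by a fixed pseudo-random permutation so discrete planted labels still mix
chromosomes within quantiles) and aggregates O/E into quantile cells (cis:
distance-normalized expected; trans: chromosome-pair block mean). The
saddle matrix is the conventional pooled mean per cell. Corner *strengths*,
however, are computed distance-stratified for cis: homotypic pairs
concentrate inside domains at short separations while heterotypic pairs
only arise across domains, so a pooled corner ratio is biased by the
unequal distance mixtures (≈1.6 where the planted affinity ratio is 2). We
therefore take, per bin-offset stratum, the corner means, and form a
weighted ratio of homotypic to heterotypic means across strata (weights:
harmonic mean of pair counts; strata with fewer than 10 pairs in either
corner dropped). This estimator returns the planted affinity ratio exactly
on noise-free maps and is stable under sampling noise. On sampled maps with
estimated EV1 the strengths run modestly high (extreme-quantile selection
correlates with noise), which cancels in the cross-state comparisons the
statistic is used for.

Switch taxonomy: a bin's category is the concatenation of its three
per-state calls; ambiguous in any state → "ambiguous"; undefined in any
state → excluded. Fractions are reported over all classified bins — the
detectable genome — with ambiguous as one of the categories.

## Insulation and boundaries

The insulation score of bin *i* is log₂ of the mean (positionally
corrected) balanced contact in the w × w diamond between bins (i−w…i−1) and
(i+1…i+w), relative to the chromosome-wide mean diamond, undefined within
*w* bins of a chromosome end and wherever the diamond is incomplete — a
partially masked diamond mixes separation offsets asymmetrically and fakes
minima. An optional moving average (`smooth_bins`, default off) trades
sensitivity for noise suppression.

Boundaries are strict local minima (plateaus take the leftmost bin) of the
high-pass-filtered score (a 25-bin moving-average trend is subtracted
first; boundaries are sub-Mb features and the residual chromosome-scale
trend would otherwise register at its elbow). Strength is the prominence of
the minimum — the gap to the lower of the two flanking maxima, in log₂
units, via `scipy.signal.find_peaks` — and strong boundaries use a strict
`> 0.1` threshold. At 2 × 10⁶ contacts on the desk genome, prominence noise
is of order 0.05–0.1, so the false-positive rate of *strong* calls on
featureless maps is depth-dependent: tens at 2 × 10⁶, none by ~5 × 10⁷.
Planted boundaries of β ≥ 0.4 are nevertheless recovered at ≥ 90 % (±1 bin)
already at 2 × 10⁶ because their prominence (≥ 0.3) sits well above the
noise. Boundary sets are compared by greedy nearest matching within
±`match_tol_bins` (default 1) per chromosome, closest pairs first, ties by
position — so the partition is symmetric under swapping inputs.

## Territories and chromosome ends

Scaled trans maps average every ordered chromosome-pair block after
rescaling to a universal n × n coordinate by length-weighted (bp-overlap)
bin averaging and dividing by the pair's mean trans contact; both axes run
p → q, so telomere clustering reads as corner peaks and centromere
clustering as an interior diagonal peak at the length-proportional
position. Telomere/centromere aggregate enrichments are means of per-block
O/E over flag-pair bins divided by the all-pairs mean. The arm-end pair
matrix reports the mean balanced contact between every pair of terminal
`end_size` (default 1 Mb) regions, normalized by the genome-wide mean trans
contact; arms shorter than `end_size` are flagged undefined, never
zero-filled. Virtual 4C is the mean balanced contact of an anchor interval
against all bins, normalized to sum 1 over the anchor chromosome's defined
bins (whole-chromosome anchors fall back to a genome-wide normalization).
The mito-nuclear score is raw-count: the mito × nuclear contact share
divided by the share expected if contacts were uniform over bin pairs.

## The generative model

Cis pair weight: s_eff^(−α₁) below the crossover s₀ (default 2 Mb),
continuously switching to the α₂ tail above it (s_eff floors at half a bin
so diagonal self-pairs stay finite); times the affinity c_{label_i,label_j}
(ambiguous bins use the heterotypic affinity, so they carry no compartment
signal); times ∏(1 − β_k) over planted boundaries strictly between the two
bins, applied below 3 Mb separation only (TADs are a sub-Mb phenomenon —
compartment-scale structure must not feel the boundaries); times w_tel
(w_cen) when both bins carry the telomere (centromere-flank) flag. Trans
weight: t_{label_i,label_j} with the same both-flagged end multipliers.
Mito-nuclear pairs get λ_mito × the mean trans weight; the mito self-pair
is zeroed. Finally the cis block is rescaled to total mass exactly f_cis
and everything else to 1 − f_cis over unordered pairs. Maps are single
multinomial draws of n_contacts over the upper triangle, so sampled totals
are exact and fixed seeds give bit-identical maps.

Switch tracks are planted per contiguous domain: domain lengths are
1 + Poisson(mean − 1) bins around a configurable mean (default 1 Mb), and
the domain categories are a random permutation of a fixed genome-wide
composition matching the category probabilities (largest-remainder
rounding). Defaults: AAA 0.165, BBB 0.199, 0.07 for each of the six mixed
orders, remainder (0.216) ambiguous. The fixed composition means planted
genome fractions realize the probabilities up to domain-length variability
(±~0.5 points at 5,700 bins) instead of drifting by ±2 points with an
independent draw per domain — the round-trip benchmarks then measure
estimator error, not generator luck. Planted per-bin EV values are
±|N(1.0, 0.15)| floored at 0.2 for A/B bins and N(0, 0.02) for ambiguous
bins, used as the orientation reference and as ground truth.

### Presets

The six presets encode the maturation trajectory; all share s₀ = 2 Mb,
c_AB = t_AB = 1, boundary spacing 1.5 Mb:

| preset    | f_cis | α₁   | α₂   | c_AA | c_BB | t_AA | w_tel = w_cen | β    | λ_mito |
|-----------|-------|------|------|------|------|------|---------------|------|--------|
| PF        | 0.70  | 0.95 | 1.05 | 2.2  | 2.2  | 1.35 | 1.0           | 0.45 | 0.8    |
| IPSC      | 0.70  | 0.95 | 1.25 | 1.6  | 1.6  | 1.15 | 1.0           | 0.40 | 0.8    |
| MN_W0     | 0.72  | 1.0  | 1.5  | 1.8  | 1.7  | 1.20 | 1.5           | 0.45 | 0.8    |
| MN_W3     | 0.78  | 1.0  | 1.7  | 2.0  | 1.9  | 1.30 | 2.0           | 0.55 | 0.8    |
| MN_W6     | 0.85  | 1.0  | 1.9  | 2.3  | 2.1  | 1.45 | 3.0           | 0.65 | 0.8    |
| ALS_MN_W6 | 0.80  | 1.0  | 1.75 | 2.1  | 1.95 | 1.33 | 2.2           | 0.58 | 1.6    |

Rationale: cis share 70 → 85 % and the α₂ steepening encode rising
territoriality and the loss of >1–2 Mb cis contacts; homotypic affinity is
strongest in fibroblasts and mature neurons and weakest at the iPSC state
(the reprogramming dip), with A slightly above B at week 6; end-region
clustering switches on at week 0 and triples by week 6; boundaries
strengthen with maturation. The ALS preset models maturation arrest: its
parameters sit between weeks 3 and 6 (close to week 3) on every
maturation axis, while its mito-nuclear leak is doubled — the background
signature of compromised mitochondrial integrity.

## What the synthetic benchmarks do and do not show

The generator reproduces the statistical structure the estimators assume:
power-law decay, block compartments, insulating boundaries, end clustering,
a cis/trans split, multinomial sampling noise. It does not emulate
restriction-fragment geometry, read-level artifacts (duplicates, religation
products), copy-number or translocation effects, loop/dot anchors,
condensin/cohesin-specific P(s) shoulders beyond the two-exponent decay, or
the correlated biological variation between clones and donors. Passing
round trips therefore demonstrate estimator correctness and calibration
under the stated model, not robustness to every artifact of real libraries.
Parameters recovered from balanced maps are also mildly damped or inflated
relative to planted values where balancing interacts with the planted
structure; orderings across presets are preserved, which is what the
cross-state comparisons consume.

## Numerical conventions and degenerate inputs

Log-spaced P(s) bins start at one bin size; curves with fewer than three
nonempty distance bins are an error. Saddle quantile cells with fewer than
10 pairs are dropped and counted. Boundary strength exactly equal to the
threshold is not strong (strict inequality). Duplicate mirrored triplet
entries, positions beyond chromosome ends, unknown presets, empty boundary
lists, all-masked matrices, subsets of fewer than two chromosomes, anchors
with no unmasked bin and genomes without a mitochondrial contig (for the
mito score) all raise explicit errors. Pipeline runs are deterministic
given seeds: reruns produce byte-identical JSON summaries.

## Problem sizes

The bundled benchmarks run at desk scale by choice: the 8-chromosome test
genome at 250 kb bins (~1,400 bins) for single-feature recovery and the
preset arc, and the 1/5-scale 22-autosome genome at 100 kb (~5,750 bins,
2 × 10⁷ contacts per state) for the switch-taxonomy round trip, where
genome-fraction estimates need both bin count and depth. These sizes keep a
full simulate → estimate cycle in seconds to about a minute per state while
leaving every statistic well-posed.
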