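# Methods

## Data model and conventions

All coordinates are 0-based half-open; bins are addressed by global
chromosome-major integer ids; the last bin of a chromosome may be short.
Contact matrices are stored as upper-triangle sparse counts; queries always
present the symmetric view. The only balancing scheme is square-root
vanilla coverage: w_i = 1/sqrt(m_i) with m_i the symmetric marginal,
balanced value w_i c_ij w_j; bins with zero marginal carry NaN weights and
propagate missingness. Balanced sqrt-VC values are invariant to global
depth by construction — a property several normalization decisions below
rely on.

`expected_by_distance` is the arithmetic mean of the (balanced or raw)
intra-chromosomal signal per bin offset, with optional isotonic
(non-increasing) smoothing via pool-adjacent-violators, off by default: the
mean is unbiased and the smoothing is only worth its bias when profiles are
extremely sparse.

## Synthetic genome and what it does (not) emulate

The default genome is 4 chromosomes x 10 Mb at 10 kb base resolution with
2 M pairs — sized so that 5 Mb-scale rules are exercisable while a full
simulation takes seconds. The background rate is (d+1)^alpha within
chromosomes (alpha = -1) and constant between chromosomes, scaled so 10% of
pairs are trans. Multiplicative structure:

- Plaid compartments: alternating 1 Mb A/B blocks; same-label cells x(1+s),
  cross-label x(1-s) with s = 0.3.
- TADs: x2 within each planted interval. Compartment-block transitions also
  act as insulating boundaries, as in real data, so boundary callers see
  both kinds.
- Loops: focal 5x5 footprint centered on the anchor pair (full fold at the
  apex, halved per Chebyshev ring) — punctate but not single-pixel, as
  loops present at finite resolution.
- Rearrangements: each junction adds a wedge on the partner block with rate
  proportional to (d_A + d_B + 1)^alpha — the distance measured through the
  junction on the derivative chromosome — restricted to the retained side
  of each breakend and scaled by the clonal fraction. The coefficient
  equals the intra-chromosomal one, so signal is continuous across the
  junction in assembly coordinates. Neo-loops are focal enrichments of this
  wedge.
- CNV: cis rates scale with min(r_i, r_j) (a cis contact requires both loci
  on the same molecule), trans rates with r_i * r_j. Bin coverage then
  tracks the planted copy ratio.

Counts are Poisson per cell (optionally gamma-Poisson overdispersed), then
expanded to a pair stream with uniform positions inside base bins, so one
draw can be binned consistently at any resolution and unique-valid-pair
(uvp) bookkeeping is exact. Background and rearrangement pairs use
independent child seeds of the master seed, so an SV-free configuration
reproduces the background stream of an SV-bearing one.

Not emulated: FFPE artifacts (same-fragment ligation, duplicates),
read-level sequence, mappability structure, GC bias, sub-bin events.
Passing tests therefore demonstrate correctness of the analysis chain on
data with the stated statistical structure, not robustness to artifacts the
generator does not model.

Emulated callers emit each planted junction with probability 1 - miss rate
under truncated-Gaussian anchor jitter, plus uniformly placed false
positives with random strands. A false positive may not mimic a jittered
true call (both anchors within 2 Mb of the same planted junction's
anchors); it may land elsewhere near real wedge signal, which is exactly
the hard case a reviewer faces. OGM call sets use the same mechanism with
independent errors and carry sizes for intra-chromosomal events.

For cohort-level statistics (differential compartments/insulation/presence,
PCA), per-sample score tracks are emulated directly (truth value plus
Gaussian sampling noise, with optional group-specific flips or shifts):
these tests concern the statistics, whose inputs are per-sample tracks, and
track-level emulation keeps 200-replicate null studies tractable.

## Breakpoint review

Candidate calls from two emulated callers are merged by union; where both
anchors fall within 1 Mb, only the preferred caller's call is kept
(greedy on smallest anchor-distance sum, deterministic tie-break, hence
order-independent). Intra-chromosomal (+,-) calls spanning <= 5 Mb are
excluded as TAD-indistinguishable unless mean anchor coverage is >= 3x the
chromosome median ("exceptionally greater" quantified as 3x), which flags
amplification instead.

Review operates on the 100 kb matrix: with 100 kb caller jitter the anchor
is within a few review bins of the truth, and the 4-bin snap window can
reach it. Corner metrics use a +-5-bin window around the anchor pair
(inter-chromosomal: balanced values; intra: observed/expected so distance
decay does not masquerade as corner signal):

- contrast: fused-quadrant mean over the **median** of the other three
  quadrant means — the median makes the reference robust to one quadrant
  contaminated by an unrelated nearby junction, which matters at realistic
  junction densities;
- decay: Spearman correlation of fused-quadrant signal with derivative
  distance |r - a| + |c - b|;
- strand consistency: the maximal-contrast quadrant equals the call's
  sides;
- snapping: each anchor moves to the bin maximizing the retained-minus-lost
  signal step of the quadrant profile within the snap window.

Procedure per call: reference-panel hits (both anchors within 1 Mb of a
panel call) are rejected; the best quadrant is detected, anchors snapped,
sides corrected; calls failing contrast >= 1.6 or decay <= -0.2 are
rejected; otherwise accepted, or adjusted when anchors or sides changed.
The thresholds were calibrated on the simulator with an ROC sweep of
true-junction versus false-positive metric distributions at the default
conditions (50 junctions per genome); at that density a stricter contrast
cut (e.g. 2.0) costs several percent recall with negligible precision gain,
because plaid modulation and neighboring wedges depress marginal true
corners. Re-running review on accepted calls is a no-op (snap and side
detection are at fixed points), giving idempotence.

## Topology

Compartment scores: per autosome at 100 kb, leading eigenvector of the
Pearson-correlation matrix of the balanced observed/expected matrix, after
dropping masked (blacklist) and zero-coverage bins; re-inserted as missing.
The chromosome's sign flips iff the Pearson correlation with the provided
H3K27ac-like track is negative, guaranteeing non-negative final correlation
whenever defined; a constant track leaves the sign as computed and sets a
flag. Chromosomes with fewer than 10 usable bins return all-missing.

Insulation: mean balanced signal in the w x w diamond crossing each bin
(w = window/resolution, default 100 kb at 10 kb), log2-normalized to the
chromosome mean; the first/last w bins are undefined; the gradient is a
centered finite difference over defined bins. The score is invariant to
global count scaling. Boundaries are local minima with prominence >= 0.4
(scipy peak prominence on the negated score), a value at which planted-TAD
and compartment-transition boundaries are retained while depth-typical
noise minima are not; boundary count is monotone non-increasing in the
threshold.

Loop calling is a single-scale donut test, deliberately simpler than
multi-window production callers. The statistic is the raw-count sum over
the 3x3 peak block: at desk-scale depth single-pixel counts are too sparse
to separate focal enrichment from Poisson extremes. The local expectation
is the maximum over three neighborhoods — donut (inner radius 2, outer 5,
cross excluded) and horizontal/vertical stripes — scaled from the
distance-decay expectation; the maximum makes the test robust to plaid
transitions crossing the donut, the same reason production callers test
several neighborhoods. Candidates need >= 10 raw pairs and 2-fold
enrichment over both the global-distance and local expectations; Poisson
upper-tail p-values are Benjamini-Hochberg-corrected **against the full
number of tested pixels**, not just prefiltered candidates (correcting only
across the selected tail would be anti-conservative). Adjacent significant
pixels collapse to the most enriched representative.

## Rearrangement interpretation

Copy number: per-bin symmetric marginals, normalized to the genome median,
segmented per chromosome by recursive least-squares binary segmentation
(minimum segment 5 bins; a split must improve SSE by more than
10 * sigma^2 * log n with sigma from successive differences). Ratios are
depth-invariant. A 1-bin event at 500 kb resolution is below the minimum
segment length and is not called — the documented resolution limit.

Assemblies chain reviewed junctions into oriented segments. Side `+` enters
the junction traversing forward (retains <= pos), side `-` reversed; middle
segments run between consecutive junctions whose sides must agree on the
retained direction (otherwise an error naming the junctions); terminal
extent is bounded by the chromosome end, the nearest CNV changepoint, or a
4 Mb flank cap (figure-scale windows). Coordinate maps are exact inverses
per segment. Junction order is explicit input — segment order is not
auto-inferred from interaction strength. The assembled matrix re-indexes
the reference matrix through the maps (segment bounds snapped outward to
the bin grid), recomputes balancing, and can divide by copy-ratio products.
Neo-loops are detect_loops calls on the assembled matrix whose anchors map
to different segments; the external tool's posterior-probability threshold
has no in-repo analog, so high confidence is operationalized as fold >= 2
with BH FDR <= 0.05, both exposed.

Virtual 4C returns the mean over viewpoint-window rows. Raw (observed)
profiles are divided by uvp for cross-sample comparability; balanced
sqrt-VC profiles are already depth-invariant and are returned unscaled —
dividing them by uvp would break invariance under joint (counts, uvp)
scaling. Both modes are invariant to that joint scaling.

## Enrichment and statistics

Permutation controls draw an equal number of uniform positions on the same
chromosomes as the observed features, excluding masked intervals, with
empirical p = (1 + #{replicates >= observed}) / (1 + R) (never zero;
finite-sample valid). Default 1,000 replicates. Compartment labels: score
> 0 is A, <= 0 is B (the boundary case assigned to B).

APA aggregates balanced/uvp windows (10 kb, +-100 kb) over anchor pairs at
least 300 kb apart; by default each window is divided by the distance-decay
expectation (O/E) first, because the lower-left corner reference block sits
at shorter genomic distance than the center and the un-normalized score is
systematically below 1 under anchor shuffling. The center score is the
central 3x3 block mean over the lower-left 5x5 corner mean — the block
matches the focal loop footprint and is far less noisy than one sparse
pixel. `oe=False` recovers plain balanced/uvp averaging.

Mann-Whitney U tests are two-sided, exact for tie-free samples with
combined n <= 12 and asymptotic with tie correction otherwise (scipy);
Fisher tests are exact two-sided; BH adjustment via statsmodels. All three
are cross-checked in the tests against exhaustive enumeration oracles
(all label assignments / hypergeometric tail sums) for group sizes <= 6.
Differential insulation at targeted loci carries no multiplicity
adjustment, matching per-locus reporting; cohort-wide compartment scans use
BH.

OGM↔Hi-C matching deviates from a naive greedy: it solves the global
assignment (maximal matched pairs, then maximal strand-concordant pairs,
then minimal total anchor distance) via a padded linear-sum assignment.
Greedy best-first can drop cardinality when candidate neighborhoods
overlap, and the global optimum is what the exhaustive small-instance
oracle verifies; the per-pair criteria (1 Mb per anchor, strands before
distance) are unchanged. Sliding windows are half-open [s, s + w), so at
step = w the counts partition the events.

## Problem sizes and calibration studies

The acceptance script and tests run: SV recovery on 5-10 genomes of 50
junctions each (2 M pairs, 100 kb jitter, 20 false calls); loop studies on
a single 10 Mb chromosome at 4 M pairs (counts per pixel high enough for
the block statistic while a 20-seed null study stays within minutes); null
calibration with 200 replicates. These sizes are chosen so the full suite
completes in about two minutes on one CPU while each check retains
statistical power.

## Known limitations

- The boundary caller is insulation-minima based, not hierarchical; the
  loop caller is single-scale. Both are documented simplifications of the
  multi-scale external tools they stand in for.
- Review recall is bounded by the 1 Mb union-merge rule at high junction
  density: when each caller sees a different member of a close junction
  pair, the merge collapses them and one junction is lost before review.
- Near-diagonal borderline events: the null false-call rate of the loop and
  neo-loop callers at FDR 0.05 is controlled but not far below the nominal
  level at desk-scale depth; occasional single borderline calls (q close to
  0.05) appear in a few percent of null genomes.
- The breakend-side convention (retained-coordinate direction) is assumed
  equivalent to external callers' +/- strands; importers of real BEDPE
  should verify the mapping.
- cooltools-style edge handling of insulation NaNs is not claimed
  identical; ours is as documented above.
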