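# Methods

## The ω statistic

For a window of `W` SNPs around a candidate position, split into a left
flank `L` of `l` SNPs and a right flank `R` of `W − l` SNPs,

    ω = [ (C(l,2) + C(W−l,2))⁻¹ · ( Σ_{i,j∈L} r²ij + Σ_{i,j∈R} r²ij ) ]
        / [ (l(W−l))⁻¹ · Σ_{i∈L, j∈R} r²ij ] ,

the ratio of average within-flank linkage disequilibrium to average
cross-flank LD.  A completed selective sweep drags one haplotype to high
frequency on each side of the fixed beneficial allele independently, so
LD is high within each flank and low across the fixation site: ω peaks at
sweep centres and is ≈ 1 under spatially homogeneous LD.

`r²` is the squared correlation of allelic states.  Binary (0/1) data use
the classical `(p_ij − p_i p_j)² / (p_i(1−p_i) p_j(1−p_j))` for the
derived/derived cell.  Multi-state DNA data sum the per-state-pair terms
over state pairs that are polymorphic at both members and scale by
`(v_i−1)(v_j−1)·v_ij / (v_i v_j)`, where `v_i ≤ 4` counts the states
present at SNP `i`.  The `v_ij` factor ("valid pairs of states") is
ambiguous in the literature; we define it as the *fraction* of samples
valid (non-gap, non-N) at both SNPs.  This keeps r² equal to the binary
kernel on gap-free biallelic columns (the four state-pair terms are equal
and the prefactor is 1/4) and bounded on gappy ones; any absolute-count
reading makes r² unbounded.  Allele frequencies are always taken over the
jointly-valid samples of the pair.

### Cumulative LD-sum table

All three region sums are served by a lower-triangular table
`M[i, j] = Σ_{j ≤ a < b ≤ i} r²_ab` filled by the dynamic-programming
recurrence `M[i,j] = M[i,j+1] + M[i−1,j] − M[i−1,j+1] + r²_ij` (rows
ascending, columns right to left; we treat the recurrence's column bound
as `j ≥ 1` in 1-based terms, since `j = 0` has no base case and
contradicts the cumulative semantics).  For a split with `l` left SNPs,
`ΣΣ_L = M[l−1, 0]`, `ΣΣ_R = M[W−1, l]`, and the cross sum is the
difference from `M[W−1, 0]`.  Because consecutive grid locations share
most of their window, the table of the next window is a diagonal
sub-block of the current one; the scan copies that block and computes
only the rows its window adds.

### Window semantics and search

A grid of `D` equidistant locations spans the polymorphic region (first
to last SNP — ω is undefined outside that span).  At each location, every
SNP strictly closer than `minwin` is mandatorily included; candidate
borders then extend one SNP at a time out to `maxwin` (inclusive).  All
border pairs with ≥ 2 SNPs per side, ≥ `minsnps` SNPs in total and (when
the balance parameter is set) a side-count imbalance ≤ `b` are evaluated
exhaustively, which guarantees the reported maximum over any incremental
enumeration order.  Ties are broken toward the smallest window, then the
leftmost left border, for cross-platform determinism.

A cross sum of exactly zero is the ideal sweep signature but makes ω
undefined; the denominator is floored at ε = 10⁻⁹ so that a perfect
pattern yields a large, finite, still-ranked value.

Defaults (`minwin` 10 kb, `maxwin` 100 kb, `minsnps` 5) follow the usual
human-data guidance; small values of `minwin`/`minsnps` make neutral LD
noise in tiny windows dominate and are avoided.

### Tiled work plan

For memory-bounded or parallel execution the SNP sequence is cut into
groups of `G` SNPs (128 by default; configurable down to 2–4 so tests can
exercise the tiling on tiny data).  Each pair of groups touched by a
candidate region is one "compute group" (a G×G r² tile); overlapping
regions share tiles through a deduplicated compute list.  An iteration's
size `T` (in groups) is the largest for which the projected tile storage
— one 8-byte float per entry, `G²` entries per tile, summed over the
compute list — fits the user's memory budget; the number `k` of grid
locations per iteration follows from which windows fit inside those
groups, and varies with SNP density.  The DP recurrence makes tile (x, y)
depend only on (x, y+1), (x−1, y) and (x−1, y+1), so tiles on one
diagonal of the tile table are independent and diagonals are processed in
ascending order; per-row accumulation runs right-to-left in the same
order as the plain scan, so tiled, threaded and sequential execution are
identical bit for bit.  Final ω evaluations are distributed over "omega
queues" balanced by total SNP count (longest-processing-time greedy).

## Comparison statistics

Implemented on binary windows with ancestral state 0 (the ms convention;
DNA input is binary-deduced first, derived = non-majority, an
approximation we document):

* θπ (mean pairwise differences), Watterson's θW = S/a_{n−1}, and Fay &
  Wu's θH from the unfolded SFS;
* Tajima's D with the standard 1989 constants;
* Fu & Li's D* and F* with the corrected (Simonsen et al.) constants;
* the normalised Fay & Wu H.  The literature sometimes prints the
  normalisation without the square root; we use (θπ − θL)/√Var with the
  Zeng et al. (2006) variance and θL = Σ i·S_i/(n−1).  θπ − θL is half
  of the original θπ − θH, and the sign convention (negative near
  sweeps) is unchanged;
* Depaulis & Veuille K (distinct haplotypes) and
  H = (1 − Σ f_h²)·n/(n−1);
* Hudson's (1987-style) moment estimator of C = 4Nc: the observed
  variance of pairwise sequence differences is equated with its neutral
  expectation θ̂ + θ̂²·h(C), where h derives from the two-locus
  correlation of pair coalescence times, (x+18)/(x²+13x+18), integrated
  over the window, and solved for C by bracketed root finding (clamped to
  [0, 10⁷]; a series expansion replaces the closed form below C = 10⁻⁴
  where it cancels catastrophically).  This is the pair-variance level of
  Hudson's estimator, without the O(1/n) sampling corrections; which
  exact variant the original comparison used is not published.

Binary deduction maps the majority state to 0 (ties: alphabetically first
symbol) so the "non-deterministic" DNA→binary conversion becomes
reproducible.  Sites with any invalid sample are dropped from statistic
windows; the classical formulas assume complete columns.

## The synthetic-data generator

Replicates come from a discrete haploid Wright–Fisher population of
`M = 2·pop_size` chromosomes with infinite-sites mutation (fresh uniform
positions; within-batch collisions resampled) and Poisson-crossover
recombination (segments alternate between the two parents of a meiosis).
Rates are parameterised by the coalescent totals θ = 4Nμ·L and
ρ = 4Nc·L of the *emulated* population, i.e. per-chromosome
per-generation rates θ/(2M) and ρ/(2M), so expected sample diversity
(E[S] = θ·a_{n−1}), SFS shape and LD decay follow the coalescent values
while the forward population stays small enough to simulate.

**Demography.** Piecewise-constant size histories are given backwards in
units of 4N generations (Table-5-style bottleneck scenarios are built
in).  One unit equals 2M forward generations, so a short epoch can map to
less than one generation; each epoch is re-expressed as an
intensity-preserving run of whole generations, with bottleneck sizes
floored at 16 chromosomes and durations extended so the epoch's pairwise
coalescent intensity (duration/size, plus the displaced base-size
background) is preserved.  The floor keeps multi-lineage coalescence
gradual instead of collapsing the sample in one generation; realised
intensities stay within ~15 % of the continuous profile (whole-generation
rounding of fractional boundaries accounts for most of the residual).

**Sweeps.** mssel-style conditioning: a beneficial-allele frequency
trajectory is drawn first by forward binomial sampling with selection
s = α/M under the same size schedule, rejected until fixation, and
aligned so fixation lands at the requested time before sampling (the
random duration feeds back into which epochs the sweep overlaps, so the
alignment is iterated to a fixed point).  The population then evolves
conditional on the trajectory: beneficial-class offspring counts follow
it, a recombinant's segment containing the selected site must come from a
parent of its own class, and the partner chromosome is drawn uniformly
from the whole previous generation.  Sampling at fixation makes the
selected site monomorphic; it never appears in the output.

Because s must stay below 1, α = 2Ns is capped below M; the default
α = 100 at pop_size = 80 gives s = 0.625, a sweep lasting ≈ 16
generations ≈ 0.025 coalescent (4N) units — the duration, and hence the
recombination-escape footprint, of a strong sweep with α on the order of
10³ in an unscaled population.  In other words the rescaled sweep is
*footprint-equivalent* to the strong-selection regime even though the
nominal α is small.

**Equilibrium and harvesting.** Each parameter set burns in one neutral
run for 8M generations (≥ 4 expected whole-sample coalescence times) and
then harvests a replicate every 3M generations; each harvest is branched
through the demographic tail — and, for sweep replicates, the conditioned
sweep phase — before sampling, so the recent history is replicate-specific.
Consecutive harvests share a small fraction of deep ancestry (a pair of
lineages has ≈ e⁻³ ≈ 5 % probability of not yet having coalesced across
one spacing); we accept this mild dependence in exchange for an
order-of-magnitude runtime reduction, and `simulate_paired` additionally
branches the neutral and sweep replicate of a pair from the same harvest
(pairing does not bias threshold calibration, which only compares sweep
scores against neutrally-calibrated cutoffs).

**What the generator does and does not emulate.** Neutral output matches
msprime's coalescent (segregating sites, Tajima's D, H′ means) under the
constant and bottleneck histories — the cross-validation test asserts
this.  It does not model gene conversion, variable mutation/recombination
maps, migration or population structure, finite-sites homoplasy, or
sequencing error; passing tests therefore speak to the method's behaviour
under clean, panmictic, infinite-sites data, not to robustness against
those real-data features.

## Detection-study design

The sensitivity/specificity methodology: 1 Mb regions, n = 50
haplotypes, a sweep fixing at the region centre; 991 full sliding windows
of 10 kb at 1 kb offset for the summary statistics (the window
construction at the right edge is unstated in the source description,
which rounds the count to 1,000; we use full windows only) and a 200-point
ω grid.  Thresholds come from matched neutral replicates via
per-replicate extrema — the 5th nearest-rank percentile of window minima
for statistics that drop near sweeps, the 95th percentile of scan maxima
for ω — so the number of windows poses no multiple-testing problem.
Sensitivity is the fraction of sweep replicates strictly beyond the
threshold; the reported sweep location is the most extreme window centre
(for ω, the argmax grid location), and the mean distance to the true
target is taken over detected replicates only (undetected replicates
report no location).  Nearest-rank percentiles (the ⌈qn⌉-th order
statistic) avoid interpolation ambiguity.

Problem sizes: the acceptance script runs 100 neutral/sweep pairs per
demographic scenario and the test suite 80, with θ = 700 (≈ 3,100
segregating sites per sample) and ρ = 400 per Mb.  The published study
used 1,000 replicates per scenario with simulation command lines that are
not reproduced in the body text; our generator conditions are therefore a
stand-in, and the study quantities are compared as tolerance-banded,
scaled-down reproductions.  Two systematic consequences of the stand-in
conditions are visible and stable across seeds: the sweep's diversity
trough is wide relative to 10 kb windows at ρ = 400/Mb, so θπ and
haplotype-heterozygosity sensitivities run above the reference values
under the mild bottleneck; and under the severe bottleneck the neutral ω
maxima are heavy-tailed (bottleneck pseudo-sweeps), which raises the
calibrated threshold and both lowers ω sensitivity and lengthens the
mean distance of detected replicates relative to the reference.  Higher
per-base recombination (narrower footprints, tamer pseudo-sweeps) would
move all of these toward the reference values; we keep the conditions
fixed rather than fitting them to the expected outcomes.

## Numerical and degenerate-input choices

* Monomorphic-over-intersection SNP pairs and pairs with fewer than two
  jointly-valid samples score r² = 0 rather than raising, so scans
  proceed over gappy data.
* Duplicate ms positions are perturbed by +10⁻⁶·region_length (later
  duplicates, input order preserved); downstream windows assume strictly
  increasing positions.
* Unphased VCF heterozygotes split as (0, 1) in sample order; 'N' and '-'
  are equivalent invalid states.
* Statistics that need S ≥ 1 (Tajima's D, D*, F*, H′) return NaN on empty
  windows with a warning; θπ, θH, K and H are well defined there.
* Grid construction with D = 1 evaluates the span midpoint.
* All randomness flows through numpy Generators seeded from a single
  user seed; identical seeds give byte-identical replicates.
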