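# Methods

This note documents the models, estimators and design choices behind `xdc`,
in the package's own terms. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Contact matrices and balancing

Analyses operate on dense per-chromosome cis matrices of binned contact
counts. Dense storage is a deliberate scale decision: nematode chromosomes
are ≤ ~30 Mb, i.e. ≤ ~6,000 bins at the 5 kb working resolution, so a dense
matrix is a few hundred MB at worst and usually far less.

*Bad-bin masking.* A bin is masked when its marginal — excluding the first
`ignore_diags` (default 2) diagonals — is zero, or when its log marginal
lies more than `mad_max` (default 5) median absolute deviations below the
median log marginal of nonzero bins. The MAD is unscaled
(median |x − median|). With strict inequality, a set of exactly equal
marginals (MAD = 0) masks nothing.

*ICE balancing.* Weights start at 1 on good bins and are repeatedly divided
by the square root of the current balanced marginal over its mean, with the
first `ignore_diags` diagonals excluded from marginals, until the
coefficient of variation of good-bin marginals falls below `tol`
(default 1e-5) or `max_iters` (default 500) is reached. This update has the
same fixed point as dividing by the scaled marginal itself; the square-root
damping is more stable on rough matrices. On exit, weights are rescaled so
the mean balanced marginal on good bins equals 1, making weight vectors
comparable across implementations up to that convention. Non-convergence
raises a warning and is recorded on the result (`converged`, `achieved_cv`)
rather than silently accepted.

## Insulation and boundary calling

The insulation score at bin *i* is the sum of balanced contacts between the
*w* bins upstream and the *w* bins downstream (*w* = window/bin_size;
default window 150 kb). The reported score is log2(sum / chromosome mean of
sums over valid bins), so it is invariant to overall matrix scale. Pixels
touching masked bins contribute zero to the sum. This choice is deliberate:
unmappable regions then produce the characteristic artefactual dips seen in
real data, and the per-bin `valid` flag (false when the diamond overlapped a
masked bin or the bin is within one bin of one) lets the boundary caller
*report* such dips while excluding them from the boundary set
(`excluded_reason = "empty_bin_adjacent"`). Setting the score to NaN there
instead would silently hide the artefact mechanism the exclusion rule
exists for.

Boundaries are local minima with prominence ≥ `min_prominence`
(default 0.1, log2 units — exposed because no principled universal value
exists). Minima are searched per contiguous finite segment of the track so
chromosome edges and gaps cannot lend spurious prominence. Boundary density
is reported per Mb of *valid* track, not full chromosome length.

## Distance decay and loop-size estimation

P(s) is the pixel-count-weighted mean balanced contact per valid pixel,
aggregated on a log-spaced grid (8 bins per decade from 2 × bin_size) and
normalised to unit sum. The slope curve is the central finite difference of
log10 P against log10 s followed by a moving average with halfwidth 2 grid
bins; both the grid density and smoothing halfwidth are exposed, because the
peak position depends on them.

Loop extrusion adds a multiplicative factor to P(s) whose log-derivative is
what carries the signal. The estimator reads the separation of the highest
interior local maximum of the smoothed slope within the search range
(default 20 kb – 2 Mb; ties to smaller s) as the mean loop size. Each
maximum's position is refined to sub-grid precision with a three-point
parabolic fit in log10 s; without refinement the statistic is confined to
grid points, which makes downstream permutation p-values badly discrete. A
monotone slope yields an *undefined* loop size with a stated reason — a
value, not an error.

## The A-vs-X permutation test

The test statistic is the difference in mean loop size, collapsed autosomes
minus X; positive when X loops are smaller. Significance comes from
re-assigning observations to the two classes without replacement, preserving
class sizes (default n = 10,000; when fewer distinct assignments exist they
are enumerated exhaustively), and counting permuted statistics at least as
extreme in absolute value.

*Observation unit.* The default unit is one slope local-maximum separation,
extracted per non-overlapping 2-Mb window of each chromosome (each window's
matrix block is re-balanced and analysed as a miniature chromosome; the
search range is capped at half the window). The windowing supplies the
within-class replication a single-X genome otherwise lacks: whole-chromosome
extraction yields one clean maximum per chromosome at realistic depth, hence
at most C(#chrom, #X) distinct assignments — with six chromosomes and one X
the smallest attainable p is 1/6, which cannot support the permutation
counts the test is meant to run. Loop extrusion is a local process, so
windows act as quasi-independent replicates of the extrusion scale and are
genuinely exchangeable between classes under the null. Two alternative units
are retained: `"curve"` (pool per-(chromosome, grid-bin) slope values and
rebuild per-class curves each permutation — its permuted class curves are
per-bin random mixtures of the class curves, which inflates the null spread
and drains power; kept for comparison) and `"chromosome"` (whole-label
permutation; granularity-limited as above).

*Ties.* A permuted statistic exactly as extreme as the observed counts
toward the p-value ("weak" convention, default): with a discrete or
partially discrete statistic this keeps the test valid (two identical groups
give p = 1, never a spurious rejection). Strict counting and an add-one
(b+1)/(n+1) estimator are options.

*Calibration harness.* `xdc.validation` simulates replicated null
(both classes share one extruder scale) and alternative (X loop size half
the autosomal) datasets on a desk-scale karyotype (5 autosomes + X, 6 Mb at
10 kb bins, 400k reads per chromosome — sizes chosen so a replicate runs in
well under a second) and reports rejection rates with Clopper–Pearson
intervals.

## Sex-biased expression and the compensation verdict

*Filters.* A gene is *expressed* when its mean TPM over replicates exceeds 1
in each sex separately. The *soma* filter keeps expressed genes with
|log2FC| < 3: germline-specific genes show sex differences of 8-fold and
more, producing a bimodal |log2FC| distribution whose antimode the cutoff
splits. Both thresholds are flags.

*Normalisation.* Size factors are median-of-ratios against the
geometric-mean reference over genes with positive counts in every sample.
When the genome model is available the reference set is restricted to
autosomal genes: an X that genuinely carries a shift moves a ~20% one-sided
block of genes, and an all-gene median absorbs part of that shift into the
factors, attenuating every fold change — anchoring on autosomes is the
standard remedy in dosage-compensation work. The per-gene statistic is
log2((mean normalised hermaphrodite + c)/(mean normalised male + c)),
pseudocount c = 0.5 (a flag). No shrinkage and no per-gene Wald tests: the
unit of inference is the chromosome, and an unshrunken estimate keeps the
soma-filter boundary interpretable.

*Tests and verdict.* Each chromosome's gene-level log2FC values are compared
to the pooled rest with a two-sided Wilcoxon rank-sum test (exact for tiny
samples, normal approximation with continuity correction otherwise).
The verdict is:

- **compensated** — the X is not individually significant at
  α/#chromosomes (Bonferroni), or its |mean deviation from the rest| and
  −log10 p both lie within the range spanned by the autosomes' own
  one-vs-rest results;
- **not_compensated** — the X is significant *and* exceeds every autosome on
  both measures;
- **inconclusive** — otherwise.

The significance gate is essential: among k chromosomes one is always the
most extreme, so a pure range rule would call ~1/k of perfectly null
datasets uncompensated. All thresholds are recorded in the verdict object.
Sub-chromosome segment means (for ancestral-unit or fusion analyses) use the
same machinery over an optional segment table.

## ChIP enrichment

Coverage tracks are step functions at a fixed step (default 10 bp; the
analysis is step-invariant for piecewise-constant tracks). Region kinds:
gene bodies (annotated start–end), TSS windows (250 bp either side of the
first transcribed base, strand-aware, truncated at chromosome edges), 10-kb
tiling bins, and the intergenic complement of merged gene bodies. Per-region
enrichment is log2((mean ChIP + 1)/(mean input + 1)); the pseudocount is a
flag, and ChIP-minus-input differences are also emitted for display parity.
Values are z-scored with the population sd across all regions of one kind
genome-wide — scoring genome-wide (not per chromosome) is what lets
chromosome-scale differences survive the transform. One-vs-rest testing is a
one-sided rank-sum per chromosome; both directions are meaningful (X
enrichment and X depletion both occur in nature), so the pipeline tests
both and reports the direction the data support.

## Synthetic data generators

The generators produce data with the statistical structure the estimators
assume; they are deliberately minimal and make no mechanistic claims.

*Hi-C.* Expected contacts fall as s^(−decay_exponent) (default 1.0).
An extruder with mean loop size L multiplies the surface by
10^(A·σ√(2π)·Φ((log10 s − log10 L)/σ)) with σ = 0.25 decades: this
antiderivative form is chosen precisely so the slope curve gains a single
Gaussian local maximum of height `loop_amplitude` exactly at log10 L — a
bump placed in P(s) itself would put the slope maximum ~σ left of the
intended location and make planted sizes unrecoverable by the estimator
that defines them. Planted domains multiply within-domain contacts by
(1 + boundary_strength), the corner pixel by (1 + dot_strength) and the
first row/column inside the domain by (1 + stripe_strength) — the three
visual criteria of a loop-anchored domain. Pixels are Poisson-sampled on
the upper triangle (scaled to `total_reads` per chromosome) and mirrored;
a random `empty_bin_fraction` of bins is zeroed and flagged. Not modelled:
polymer kinetics, trans contacts, compartments, replicate structure.

*Expression.* Per-gene sex effects come from a two-component mixture —
soma: Normal(0, 0.5); germline: ±Normal(4.0, 0.5) with random sign
(drawn per gene, so bimodality appears in |log2FC|). The germline sd of 0.5
places ~98% of germline genes beyond the 3-cutoff, matching the observation
that germline genes show >8-fold differences. Germline genes are depleted
from the X by default (half the autosomal fraction). X-linked soma genes
get an extra `x_imbalance_log2` (0 = compensated; 1 = uncompensated
two-fold). Effects split symmetrically between sexes
(herm × 2^(b/2), male × 2^(−b/2)), so exchanging sex labels is exactly a
sign flip. Counts are negative binomial (var = μ + 0.05 μ²) at library size
2 × 10⁶ with 3 replicates per sex. Not modelled: batch effects, isoforms,
GC/length bias beyond the explicit length factor.

*ChIP.* Input = flat background (20) + Gaussian noise (sd 2), clipped at
zero; ChIP multiplies the clean background by 2^gene_body_signal inside
gene bodies and 2^x_log2_effect on X chromosomes, then adds its own noise.
Not modelled: fragment-length smearing, copy-number structure, antibody
efficiency differences between replicates.

Because the generators are minimal, a passing suite demonstrates that the
estimators recover what they are defined to measure and that the tests are
calibrated under exchangeability — not that real libraries satisfy these
assumptions. Mapping artefacts, compartment structure and replicate
variance in real data are outside what these checks can certify.

## Pipeline verdict rules

`x_specific_extruder` = permutation p < 0.05 with a positive observed
A−X difference. `x_specific_tads` requires the X to carry ≥ 3 accepted
boundaries, more than all autosomes combined, and a higher per-Mb density
than the densest autosome — noise dips produce a background of ~1–2
prominence-0.1 calls per chromosome at simulation depth, and the
combined-count requirement keeps that background from being read as
structure. Absent inputs make a stage "untested", never a default verdict.
Reports carry the config hash and seeds, and re-running a config reproduces
the report byte for byte.

## Numerical notes and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds reproduce byte-identical
  outputs.
- Diagonals with no valid pixel are NaN gaps everywhere, never zeros; gaps
  propagate through differentiation and smoothing.
- Local-maxima detection ignores sub-1e-9 differences so an exactly flat
  slope has no maxima; plateaus resolve to their left edge.
- Zero-read simulation yields all-zero matrices with every bin flagged
  empty; requesting structure on zero reads is an error.
- An all-bad matrix, a zero-total expression sample, a constant enrichment
  vector (sd = 0) and a zero-width region are errors with explicit messages.

## Known limitations

- The permutation test's windowed observation unit assumes extrusion
  statistics are homogeneous along a chromosome; a chromosome with strongly
  position-dependent loop sizes would violate window exchangeability within
  its class.
- The loop-size estimator reports the single highest slope maximum;
  multi-scale looping (nested/consecutive regimes) is summarised by one
  number and the remaining maxima only enter through the permutation
  observations.
- The compensation verdict is relative to the autosomes of the same genome;
  it cannot detect a shift shared by every chromosome.
- cis-only throughout; trans pixels in input files are ignored (counted in
  the log).
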