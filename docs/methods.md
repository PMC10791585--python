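# Methods

This note documents the models, conventions and design choices behind
`dispkit`, in the order data flows through the toolkit.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); an
interval of length L covers exactly L bases and abutting intervals never
overlap. 1-based conventions (SAM positions, residue numbering in
disorder-region files) are converted at the file boundary only.
Chromosome names are matched by exact string equality — no "chr" aliasing
— so fixture mismatches fail loudly rather than silently returning empty
overlaps. The narrowPeak/broadPeak q-value column is read as −log10(q)
per the UCSC definition, so the q < 10⁻⁵ peak filter corresponds to a
column value above 5.

## Fragment coverage

Whole precipitated fragments are reconstructed from proper read pairs by
filling the gap between mates: each fragment spans the minimum mate start
to the maximum mate end. Improper pairs (different chromosomes, or the
proper-pair flag unset) are dropped and counted. Duplicates are defined
by exact fragment coordinates — both ends identical — the deterministic
paired-end analogue of coordinate-based duplicate marking.

Tracks store the mean per-base fragment depth per bin at a default
resolution of 10 bp. This is display-scale resolution: at the 1-kb
windows used for quantification the binning error is negligible, and a
10-bp track of a mammalian-scale genome fits comfortably in memory. The
final bin of a chromosome may be narrower than the resolution; actual bin
widths are used wherever mass is integrated, so the track integral equals
`scale_factor × Σ fragment lengths` exactly (tested to 10⁻⁶ relative).
Normalization multiplies the pileup by `target_reads / library_size` with
a 10 M target, which makes the track invariant to uniform duplication of
the library.

Per-locus signal is the arithmetic mean of normalized depth over a 1-kb
window centered on the locus midpoint. Window overhang beyond a
chromosome end is excluded from the mean (not zero-padded), avoiding edge
artifacts; a window with no in-bounds bases returns 0. Composite matrices
tile ±5 kb around region midpoints in 100-bp bins, each cell being the
mean track value over its tile; with strand awareness enabled, minus-strand
rows are reversed.

The threshold peak caller exists to close the loop on synthetic data; it
is not a model-based caller (no local background model, no FDR control).
It reports maximal runs of bins at or above a threshold, bridges
sub-threshold gaps up to a merge distance, and discards runs shorter than
a minimum length. The pipeline wrapper expresses the threshold as a
multiple (default 5×) of the genome-wide mean depth so it transfers
across library sizes. Peak signal downstream of the caller is the 1-kb
window mean; integrated depth over the peak body is available as an
option because either reading of "total signal" is defensible.

## Peak annotation

Promoter/distal classification measures the edge-to-TSS distance
(0 when the TSS lies inside the peak) with an inclusive 2-kb radius —
"within 2 kb" is taken to include the boundary, and edge rather than
summit distance is used because summits are not always available.
Dominant-state assignment counts overlapped bases per chromatin state
within each peak; uncovered bases count as `background`. Ties are broken
by a fixed priority order — the segmentation's state order, most active
first, with background always last — because a dominant-overlap rule
needs a deterministic tie-break to be testable.

## Island calling

Peaks whose edge-to-edge gap is at most 20 kb are stitched transitively
into merged regions (chains may exceed 20 kb overall, as with standard
distance merging); a region's total signal is the sum of its constituent
peak signals.

Regions are sorted ascending by total signal and both axes are min–max
scaled to [0, 1] (scaling by the maximum alone gives identical island
sets when the minimum is small; min–max is used so the curve always spans
the unit square). The cutoff is the discrete tangent point of slope 1:
writing c_i = y_i − x_i, the point minimizing #{j : c_j ≤ c_i}, i.e. the
point the diagonal touches first when slid up from below the curve. This
is the established discretization of the hockey-stick criterion used for
super-enhancer calling; a finite-difference slope crossing agrees with it
on convex monotone curves. Ties break toward the higher index, which
yields fewer islands — the conservative choice. Islands are the regions
with total signal strictly greater than the cutoff signal ("beyond" the
tangent point, so the tangent region itself is excluded). Degenerate
conventions, chosen once and tested: a single region is an island; when
all signals are equal the cutoff sits at the top and no region is an
island.

The implementation runs in O(N log N) via sorting/searchsorted and is
verified for exact agreement against an exhaustive O(N²) scan on random
vectors up to length 200, including heavily tied inputs.

## Two-condition comparison

The union site set pools peaks from both conditions and collapses
overlapping ones (≥ 1 shared base) into single sites, preventing double
counting. Per condition, replicate window signals are averaged first and
the fold computed afterwards. Folds use a pseudocount of 1 normalized
read on the 1-kb window scale (configurable), which bounds folds at empty
sites; classification is strict — a site must change by more than the
threshold fold (default 2) to be called up or down, so an exact twofold
change is "unchanged". With a symmetric pseudocount, swapping conditions
exchanges up and down exactly.

Lost islands are those of condition A overlapping no island of condition
B (≥ 1 bp), and vice versa for gained. Lost islands are pattern A when
they contain at least one anchor-factor peak, else B; gained islands are
pattern C when they contain at least one partner-factor peak with a
>2-fold increase, else D. Distance stratification assigns each subject
peak its nearest-anchor edge-to-edge distance (0 for overlap) and bins it
with left-closed, right-open boundaries at 150 bp, 1 kb and 5 kb; group
comparisons use plain two-sided two-sample t-tests. Island→gene
association links genes within ±100 kb (edge-to-edge) of an island span
and retains those with expression fold ≥ 2 and condition-B expression
≥ 5 (inclusive, as the thresholds are written); the RNA-level
differential filter (fold 1.5, p < 0.05) is likewise inclusive on the
fold for consistency. Expression model fitting itself is out of scope —
the filters consume a precomputed table.

## Disorder statistics

IDRs are called from per-residue scores as maximal runs with score ≥ 0.5
(inclusive at the threshold) of at least 50 residues. Annotated disorder
regions are 1-based inclusive in files and merged to a union internally,
so total disorder length never double-counts overlapping annotations.
Large-IDR proteins have total disorder strictly greater than 100
residues.

The permutation test draws n_perm = 3,000 size-matched samples (matching
set size only; length-stratified matching is available but off by
default) without replacement from the background proteome and compares
the median total IDR length (or the large-IDR fraction). The empirical p
uses the add-one rule, p = (1 + #{perm ≥ obs}) / (n_perm + 1), standard
practice that keeps p strictly positive; its floor is therefore
1/3001 ≈ 3.3 × 10⁻⁴. Far smaller p-values reported for this kind of
comparison cannot come from a 3,000-draw empirical permutation, so the
z-score against the permutation null, its normal-tail p, and a one-sided
rank-sum p on the underlying lengths are reported alongside. Under the
null the empirical p is exchangeable-exact and slightly conservative in
the presence of ties (integer lengths), which the calibration test
accounts for.

Amino-acid composition is computed over the 20 canonical residues
(others counted but excluded), frequencies summing to 1 per set; the
log2 foreground/background ratio applies a configurable frequency floor
(default 10⁻⁴) so absent residues stay finite.

## The synthetic-data generators

The genomic generator emulates the statistical structure the pipeline
assumes: a uniform fragment background, isolated enriched peaks, and
island clusters. Defaults define the standard test landscape: a 2 × 5 Mb
genome, 50,000 background fragments (≈1× per-base depth given the ~206-bp
mean fragment length), fragment lengths lognormal with median 200 bp
(σ = 0.25, clipped to 50–600 bp) echoing MNase-released fragments, 20
island clusters of 6 peaks spaced 2–15 kb apart (safely under the 20-kb
stitch rule), 150 single peaks, all features separated by > 21 kb, peak
widths lognormal with median 900 bp, and 10× enrichment. Planted peak
fragment counts are deterministic given the layout
(`(multiplier − 1) × depth × width / mean_len`), so library totals are
exact; fragment positions are drawn per replicate. Condition B rescales
planted extra fragments per feature: 4 islands are lost (planted signal
×0.1), 4 extra clusters appear only in B, and 15% of singles each go up
(×4) or down (×0.25). A separate anchor-coupling generator produces
subject/anchor pairs whose condition-B signal loss decays exponentially
with distance (scale 500 bp), the structure behind the distance-stratified
analysis.

The proteome generator draws total disorder length from a lognormal with
median 31 residues and σ = 1.3915 — calibrated analytically so that 20%
of background proteins exceed 100 disordered residues; both values then
emerge from construction rather than being asserted. The precipitated
subset is sampled without replacement with weight ∝ length^0.7716, which
for a lognormal shifts the median to ≈ 31 · exp(0.7716 σ²) ≈ 138
residues — a 4.5-fold shift. Disorder is split over 1–3 annotated
regions separated by ordered linkers; IDR sequences are drawn from a
composition tilted 2× toward G/Y/K (multiplier 1 gives the null).

What the generators do **not** emulate: mappability and GC structure,
sequence content (no read bases, no repeat motifs), fragment-length
dependence on chromatin, overdispersion between replicates beyond
sampling noise, and real proteome length/composition covariance. Passing
tests therefore demonstrate algorithmic correctness and calibration under
the stated statistical model, not robustness to artifacts of real
libraries.

## Problem sizes and numerics

The test suite and the acceptance script run the pipeline at the 2 × 5 Mb
/ ~60k-fragment scale (about a second per landscape), 20 seeds for island
recovery, 200 null runs at 999 permutations for calibration, and 100 runs
at 499 permutations for the enriched regime — sizes chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo bands
tight enough to be meaningful. Track arithmetic is float64 throughout;
bedGraph output prints shortest round-trip float representations so
write→read is exact. The cutoff scan, IDR run-calling and peak caller all
operate on sorted arrays or boolean run-length encodings with explicit,
documented tie-breaks; there is no iterative optimization anywhere in the
toolkit, hence no convergence tolerances.

## Known limitations

- The threshold peak caller is intentionally simple; on real data a
  model-based caller should be used upstream and its output consumed via
  the standard peak formats.
- Window signal inherits the track's bin resolution; exact per-base
  quantification requires resolution 1, at a memory cost.
- The pattern C/D rule keys on the partner factor's "up" class from the
  same strict fold rule as the differential table; a different partner
  threshold requires reclassifying the partner table first.
- `interval_jaccard` is quadratic in the number of merged blocks; it is
  meant for island-scale set comparisons, not genome-wide fragment sets.
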