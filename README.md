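# dispkit

A Python toolkit for analysing **DisP-seq** data — disordered-protein
precipitation followed by DNA sequencing. DisP-seq maps DNA-associated
intrinsically disordered proteins genome-wide without antibodies: native
protein–DNA complexes are released by MNase digestion, disordered proteins
are precipitated with biotinylated isoxazole (b-isox), and the
co-precipitated DNA is sequenced. The resulting profiles contain thousands
of peaks, many of which cluster into large **DisP islands** — regions with
high local concentrations of disordered proteins that reorganize when
cellular state changes (e.g. depletion of a disordered oncogenic fusion
factor).

`dispkit` implements the computational side of this assay for analysts
working with such data (or benchmarking the method on synthetic data):

- **Fragment coverage** — reconstruct whole precipitated fragments from
  paired-end alignments by filling the gap between mates, deduplicate by
  exact fragment coordinates, normalize pileups to 10 M fragments, and
  quantify signal as the mean normalized depth in 1-kb windows.
- **Island calling** — stitch peaks within 20 kb into merged regions,
  rank regions by total signal, and call islands with the tangent-slope-1
  cutoff on the min–max-scaled rank–signal curve (the hockey-stick
  criterion familiar from super-enhancer analysis).
- **Peak annotation** — q-value filtering (q < 10⁻⁵), promoter/distal
  classification (±2 kb of a TSS), dominant-overlap chromatin-state
  assignment against a ChromHMM-style segmentation.
- **Two-condition comparison** — union peak tables with replicate-averaged
  signals, strict >2-fold up/down classes, lost/gained island sets,
  pattern A–D island classification (anchor-factor content of lost
  islands; up-regulated partner-factor content of gained islands),
  distance-stratified co-binding changes, and island→gene association
  within ±100 kb with expression filters (fold ≥ 2, RPKM ≥ 5).
- **Disorder statistics** — IDR calling from per-residue disorder scores
  (score ≥ 0.5 over ≥ 50 residues), total-disorder-length summaries
  (large-IDR proteins have > 100 disordered residues), size-matched
  permutation enrichment tests (3,000 draws), and amino-acid composition
  of IDR sequences.
- **Synthetic data** — generators that plant peaks, islands, two-condition
  fold changes and disorder-enriched proteomes with known ground truth, so
  the whole pipeline is testable without downloads.

## The island cutoff

Given merged regions with total signals $s_1 \le \dots \le s_N$, scale
rank and signal to the unit square: $x_i = (i-1)/(N-1)$,
$y_i = (s_i - s_1)/(s_N - s_1)$. The cutoff is the discrete tangent point
of slope 1: the index $i$ minimizing
$\#\{\,j : y_j - x_j \le y_i - x_i\,\}$ — i.e. the point touched first by
the diagonal slid up from below — with ties broken toward the higher index.
Islands are the regions with total signal **strictly above** the cutoff
signal. `compute_cutoff_index` implements this in $O(N\log N)$ and is
tested for exact agreement against an exhaustive scan.

## Worked example

```python
from dispkit import simulate_disp_dataset, islands_from_fragments, interval_jaccard
from dispkit.islands import island_summary

sim = simulate_disp_dataset(seed=7, conditions=("A",), n_replicates=1)
fs = sim.fragments[("A", 0)]                      # ~60k fragments, 2 x 5 Mb genome
result = islands_from_fragments(fs, sim.genome)   # track -> peaks -> islands
summ = island_summary(result.islands)
called = [r.interval for r in result.islands.islands]
print(f"peaks called: {len(result.peaks)}")
print(f"merged regions: {summ.n_regions}, islands: {summ.n_islands}")
print(f"median island span: {summ.median_island_span:.0f} bp")
print(f"median single-peak span: {summ.median_single_peak_span:.0f} bp")
print(f"island signal fraction: {summ.island_signal_fraction:.1%}")
print(f"Jaccard vs planted truth: {interval_jaccard(called, sim.truth_islands['A']):.3f}")
```

Output:

```
peaks called: 270
merged regions: 168, islands: 22
median island span: 48955 bp
median single-peak span: 855 bp
island signal fraction: 45.1%
Jaccard vs planted truth: 0.995
```

The simulated landscape plants 20 island clusters (6 peaks each, spaced
under the 20-kb stitch rule) and 150 isolated peaks on a uniform
background at 10× enrichment. The caller recovers the planted islands
almost exactly (base-pair Jaccard 0.995); islands are ~50× longer than
single peaks and concentrate a disproportionate share of total signal —
the qualitative signature the method is designed to detect.

The same workflows are available from the shell via the `dispkit` CLI
(`fragments`, `track`, `matrix`, `annotate`, `islands`, `diff`,
`patterns`, `disorder`, `simulate`, `run`); `dispkit run` executes the
whole single-sample pipeline and writes a manifest with content hashes.

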