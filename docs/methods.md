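# Methods

## Coordinate and orientation contract

All coordinates are 0-based half-open (BED convention). Anchors (TSSs,
dyads, motif hits) are single base pairs; a minus-strand BED interval
anchors at `end − 1`, so an anchor names exactly one bp on either
strand. Every anchor-aligned operation is strand-oriented: window
sequences are reverse-complemented, and signal windows reversed, for
minus-strand anchors, so "offset +10" always means 10 bp downstream in
gene/motif orientation. This contract is enforced by mirror-symmetry
tests: running any profile, feature or dyad operation on the
reverse-complemented genome with strand-flipped anchors and mirrored
fragments reproduces the output exactly.

## Dyad tracks

Paired-end fragments are reduced to their centers (`start + len//2`;
the floor rule for even lengths is arbitrary but fixed, so oracles can
reproduce it). Single-end reads are shifted 73 bp from the 5′ end
toward the dyad (half the 147-bp nucleosome footprint) and extended to
a 50-bp window. The extension is dyad-centered, `[d−25, d+25)`; the
alternative (read-anchored extension) is not offered because coverage
around the dyad is the quantity every downstream stage consumes.
Windows are clipped at contig ends rather than dropped — tiles are
short and silent dropping would bias tile edges invisibly; clipping is
logged.

## Nucleosome callers

**Greedy caller.** Dyad counts are convolved with a normalized Gaussian
of 101 taps (width parameter 100, interpreted as the kernel window; an
alternative reading — width as ±range — differs only in far-tail mass),
mean 0, σ = 25 bp, zero-padded at edges. Iteratively, the unmasked
maximum is recorded and positions within ±120 bp are masked; the loop
stops when no unmasked value is positive. Ties take the leftmost
position — determinism matters because the acceptance oracle replays
the same decisions. Of the recorded centers, the top `ceil(0.9·n)` by
score are kept, ties at the cut resolved in recording order. The
output's pairwise distance therefore always exceeds the exclusion zone.

**FFT caller.** Fragments are trimmed to 40 bp around their centers and
coverage computed. Per contig, the rFFT is taken and only the DC term
plus the lowest `ceil(0.02 · N_freq)` non-DC components retained
(`N_freq` = number of non-DC rFFT bins); no padding or windowing is
applied, and edge ringing is accepted — contigs model library tiles
whose edges are excluded downstream anyway (250-bp border filter).
Peaks are strict local maxima of the filtered signal above the 99th
percentile of that contig's filtered values (zeros included; per-contig
scope matches per-tile processing of a plasmid library). Positions 0
and L−1 cannot be strict local maxima. No merging of nearby maxima is
performed.

**+1/−1 annotation.** The +1 is the call minimizing |dyad − TSS| among
calls 0–500 bp downstream of the TSS in gene orientation —
nearest-by-distance, not highest-scoring, which is the literal reading
of "nearest to a TSS". The −1 is the nearest call strictly upstream of
the +1. Genes without a candidate carry explicit undefined entries and
are excluded from downstream means.

## Cross-condition clustering

Per-sample called dyads are enlarged to 20 bp (±10, symmetric), merged
across samples by interval union, and the joined regions filtered:
regions coming within 250 bp of a tile border (contig ends plus any
annotated internal boundaries) or overlapping a blacklist are removed.
Joining precedes filtering. Fragment centers are counted per region and
sample; each sample column is normalized as
`v = log2(((x/sum(x))·1000) + 0.001)`, where `sum(x)` runs over regions
— the identity `Σ_r 2^v − n·0.001 = 1000` per sample is asserted in
tests. A sample with zero counts in all regions is a hard error.

PCA treats regions as observations and samples as variables, centered
but not scaled: the normalized occupancies already share a log2 scale,
so scaling would only amplify low-variance samples (an option exposes
scaled PCA). Component signs are fixed by making the
largest-magnitude loading positive. K-means runs on all principal
components by default — Euclidean-equivalent to clustering `v` itself —
with k-means++ initialization, 25 seeded restarts, best inertia; labels
are renumbered 1..k by decreasing cluster size. Cluster summaries are
mean `v` per (cluster, sample); display rows are z-scored across
samples (ddof 1, zero-variance rows set to 0) and ordered by
average-linkage hierarchical clustering.

## DNA shape and mechanics

Pentamer shape features are table lookups (position i takes the value
of the pentamer centered on i), smoothed with a centered 5-bp rolling
mean. Undefined values (sequence ends, N-containing pentamers) are NaN
and propagate through smoothing — no shrinking windows, avoiding silent
edge bias. The real pentamer parameter tables are consumed as TSV
input, not bundled; tests use toy tables.

The rigidity score of position i is the length of the longest
substring matching AⁿTᵐ (n ≥ 0, m ≥ 0, n + m ≥ 2) that contains i;
positions in no such element score 0 (read as "no rigidity
contribution"). The implementation is linear over the run-length
decomposition: a position inside an A-run can at best extend through
its whole run plus an immediately following T-run, and symmetrically
for T-runs. It is verified exactly against an exhaustive substring
enumerator on a thousand random sequences, and satisfies
reverse-complement symmetry (AⁿTᵐ ↔ AᵐTⁿ) and invariance under G/C
padding.

Poly(dA)/poly(dT) coverage counts every, possibly overlapping, A⁶ (T⁶)
hexamer match, adding 1 to each of its 6 positions; a binary mode is
offered since composites are insensitive to the distinction. Count mode
is the default (mirrors exhaustive pattern matching).

## Profiles and grouping

Composite profiles average strand-oriented windows
`[pos−halfwidth, pos+halfwidth]` (2001 bp at the default halfwidth
1000); per-anchor normalization divides each window by its own mean
(divide-by-max offered), dropping zero-mean windows. Heat maps sort
rows by a key (NDR length, Reb1 signal score, custom), descending, ties
by anchor id. The Reb1 signal score is the mean over a 120-bp window
whose downstream edge lies 160 bp upstream of the +1 dyad (measured
from the dyad, in gene orientation). Promoter grouping retains Reb1
hits with a PWM match within ±50 bp that lie within 400 bp upstream of
a +1 dyad; group 1 = PWM on the sense strand, 2 = antisense, 3 = the
site serves two divergent genes, overriding 1/2. +1 distance statistics
use the same TSS rule for both annotation sets (symmetric definition;
nearest-matching is an option) and report gene-oriented signed
distances with median and IQR. Dyad densities are offset histograms
normalized to integrate to 1, so they are invariant to sequencing
depth.

## Synthetic data generator

The generator emulates genome-wide in vitro reconstitution on a tiled
library: independent tiles (default 50 × 10 kb — enough regions for a
stable 8-cluster K-means while keeping a desk-scale run), i.i.d.
background sequence at GC 0.38 (yeast-like), 3 genes per tile with
alternating strands. Per gene, relative to the true +1 dyad in gene
orientation: a rigid element `AAAAAATTTTTT` (rigidity 12,
reverse-complement invariant) centered at −100; a flexible element
`TACGTACGTACG` (TpA steps and G/C only, rigidity 0) centered at −55; a
Reb1 motif `TTACCC` whose gene-oriented start is exactly 145 bp
upstream of the dyad; the TSS 60 bp upstream of the dyad (typical yeast
+1 geometry). An alternative dyad 70 bp downstream of the true +1
carries a weak A-tract (`AAAAA`) 100 bp upstream of itself, giving the
assembly-only condition a distinguishable sequence-linked preference.

Conditions differ only in the dyad-choice distribution: each fragment
is background (uniform center) with probability 0.3, otherwise centered
on the condition's preferred dyad with probability 0.8 (the other
planted dyad otherwise), plus Gaussian jitter (σ = 5 bp, rounded
half-to-even). Fragment lengths follow a normal(147, 10) clipped to
[120, 180]. Fragments crossing a contig end are resampled with bounded
retries.

What the generator does **not** model: MNase sequence bias and end
preferences, nucleosome–nucleosome phasing and density effects,
histone-variant or remodeler-ruler behavior, mappability artifacts.
Passing recovery tests therefore demonstrates that the pipeline's
statistics recover planted dyad-level and sequence-level structure
under realistic noise — not that real libraries are free of the biases
above.

## Benchmark metrics and problem sizes

`run_synthetic_benchmark` (and `scripts/acceptance.py`) uses 50 tiles ×
10 kb, 2 conditions × 2 replicates, 2×10⁵ fragments per sample — sizes
chosen so one run yields ~300 joint regions (two per gene) and stable
metrics in a few seconds on one CPU:

* **+1 recovery** — fraction of genes whose greedy-called +1 (pooled
  replicates of the true-+1-preferring condition) lies within ±20 bp of
  the planted dyad;
* **cluster ARI** — regions are labeled by the planted dyad nearest
  their midpoint (within ±30 bp, i.e., unambiguous at the planted 70-bp
  dyad separation); K-means clusters are aggregated by which condition
  has the higher mean occupancy score and compared to those labels;
* **rigidity extrema** — offsets of the composite maximum and of the
  minimum between that maximum and the dyad, over recovered +1 windows
  (±160 bp);
* **density mode** — bin center (5-bp bins) of the Reb1-anchored dyad
  density; the planted distance is 145 bp, so the mode is expected
  within half a bin of +145 plus the sub-bin recovery shift.

## Numerical choices and degenerate inputs

Seeds: every stochastic step (simulation, K-means) takes an explicit
seed; the benchmark derives per-sample seeds from the master seed via a
seeded generator, keeping all below 2³¹. Degenerate inputs are
explicit: empty fragment sets give empty tracks; all-zero tracks give
empty call sets; constant tracks have no strict local maxima; a
zero-count sample is a hard error naming the sample; zero-variance
cluster rows z-score to 0. bedGraph output writes full-precision float
reprs so track round-trips are exact.

## Known limitations

The FFT caller's ~100-bp low-pass resolution (at `pc_keep_comp` 0.02 on
10-kb tiles) cannot resolve dyads closer than ~50–100 bp; closely
spaced alternative positions blur into shifted single calls, which the
joint-region logic then represents as nearby separate regions per
condition. The greedy caller's exclusion zone (±120 bp) enforces
mononucleosome spacing and will merge genuinely overlapping alternative
positions into one call. Neither caller models fuzzy or overlapping
nucleosomes.
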