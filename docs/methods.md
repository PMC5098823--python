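# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, the parameter defaults and why they were chosen,
and the known limitations.

## Coordinate system

A chromosome is a single circular sequence over {A, C, G, T, N} with a
0-based *oriC* anchor. A linear position maps to the signed offset
`((pos − oriC) mod L)` band-reduced to (−L/2, L/2]; the mapping is a
bijection and positive offsets follow increasing linear coordinate (the
"right replichore"). Nothing ties this sign convention to sequence
orientation, so `flip_replichores` inverts it when a genome's annotation
runs the other way. Internal coordinates are 0-based half-open (BED
convention); text tables print 1-based starts for readability.

## Motif scanning

The scanner computes, for every window on both strands (wrapping
pattern−1 bases across the origin on circular genomes), the Hamming
distance to an IUPAC pattern. Degeneracy is honoured in the pattern
only; an N in the genome matches no pattern letter. This asymmetry keeps
counts conservative and reproducible.

Counting is locus-level: overlapping hits are merged and represented by
the best hit (fewest mismatches, plus strand on ties, then lowest
start). This matters because the *parS* consensus `TGTTCCACGTGGAACM` is
palindromic under IUPAC matching — its reverse complement is
`KGTTCCACGTGGAACA`, which the same site satisfies — so strand-level
counting would report every site twice at zero or one mismatch.

## ChIP-seq enrichment

*Coverage.* Reads are counted as full fragment-overlap coverage;
single-end 5′ positions can be extended to a configurable fragment
length (default 500 bp, the lower midpoint of typical 0.5–1 kb
sonication). Intervals wrap circularly; an empty read set is an error
because total-read normalization would be undefined.

*Smoothing.* Centered circular moving average, default 200 bp (a
fragment-size proxy); even windows are bumped to the next odd value.
The mean filter conserves total mass, so it does not perturb the
normalization. Whether one smooths 5′-position counts or full coverage
is a user choice; full coverage is the default.

*Fold ratio.* Both tracks are smoothed, a pseudocount (default 0.5 raw
counts) is added to each, each is divided by its library's total read
count, and the per-base fold is their ratio. The pseudocount keeps the
ratio finite at zero-input bases and is symmetric, so swapping libraries
inverts the profile. Multiplying either library's counts and total by
any constant leaves the profile unchanged.

*Peaks.* Maximal runs with fold ≥ threshold (default 10; a stricter 15
is available by flag for high-background strains), with optional gap
merging (default 0) and a minimum width (default 1 bp). A run crossing
the origin is reported once with `end > L`. Peaks are ranked by
descending maximum fold, a deterministic stand-in for "most abundant
regions first". Spreading width at an anchor is the width of the
super-threshold run containing it; anchors in sub-threshold territory
report width 0 with a warning. Peaks at least `spread_min` (default
2000 bp) wide are classified "spreading", narrower ones "point" —
secondary-site-like.

## Tn-seq competence zone

Bins are anchored at *oriC* (edges at `oriC + k·bin_bp` on the circle,
default 10 kb) so zone boundaries read directly as signed offsets. The
per-bin statistic is the log2 ratio of pseudocounted (ε = 1 read),
total-normalized insertion read counts, test over control. Read counts
are the default numerator ("insertion numbers" normalized to library
totals); distinct insertion sites are available by flag for libraries
with heavy PCR duplication.

The zone is the maximal contiguous super-threshold run of bins
containing — or, failing that, circularly nearest to — *oriC*, ignoring
runs shorter than `min_run_bins` (default 3). An optional
`merge_gap_bins` (default 0) bridges short sub-threshold dips, which
individual bins produce by chance in sparse libraries. No super-threshold
run yields an empty-zone result, not an exception.

The default CLI threshold is +1 log2 sustained over ≥ 3 bins,
appropriate for the strong insertion biases seen in real libraries. For
a *k*-fold planted selection over a zone occupying fraction *f* of the
genome, total-read normalization places the expected in-zone level at
`log2(k/ (k·f + 1 − f))` and the out-zone level at `log2(1/(k·f + 1 − f))`;
the natural detection threshold is their midpoint. For the 4-fold
simulations used throughout the tests this midpoint is ≈ 0, which is the
threshold those tests pass explicitly.

## Foci statistics

Cells are oriented either randomly (each flipped with probability 1/2
under the run seed, which is recorded in output metadata) or so a
reference channel's focus lies nearer pole 0; cells missing the
reference focus are excluded and reported. Interfocal distance is
|p1 − p2| over cells with exactly two foci in a channel —
orientation-invariant; other counts are skipped and tallied. Quartiles
use linear interpolation between order statistics (one of several
conventions; fixed here for reproducibility), whiskers reach the most
extreme non-outlier points, and outliers are values 1.5×IQR or more
beyond a quartile (degenerate distributions with IQR = 0 produce no
outliers). Repartitions count (n_A, n_B) focus categories with
percentages among foci-containing cells and the no-focus fraction
reported separately. The three-foci classification considers cells with
exactly three foci across the two channels: (2,1) means the A locus
separated first, (1,2) the B locus; other three-focus patterns are
excluded and counted. The anucleate percentage carries a seeded
percentile-bootstrap confidence interval (default 1000 resamples, 95%).
No cell-inclusion filter (minimum length, division state) is applied by
default.

## Synthetic-data models

All generators are pure functions of (parameters, seed) and emit truth
records for recovery tests.

*Genomes.* I.i.d. bases at a chosen GC (default 0.5; the tests use 0.66
where a *P. aeruginosa*-like composition matters), with motifs planted
verbatim — IUPAC degeneracies resolved uniformly at random and recorded.

*ChIP reads.* Input fragments are uniform. IP fragment midpoints follow
a density `1 + Σ (h−1)·exp(−d/λ)` over anchors, i.e. exponential decay
of occupancy with circular distance — a one-parameter stand-in for the
spreading profile, whose true shape in this organism is unknown.
Midpoint (rather than 5′-start) placement makes expected coverage peak
at the anchor. The closed-form companion `expected_fold_profile`
convolves this density with the fragment box and the smoothing window
and normalizes by the genome-wide mean; it is the truth that recovery
tests compare against. Two attenuations make the realized fold at an
anchor smaller than the nominal peak fold *h*: the double box
convolution, and total-read normalization (reads concentrated in peaks
depress the IP background genome-wide). Reference conditions for the
recovery tests: 1 Mb genome, four spreading anchors (h = 30, λ = 4 kb),
eight point sites (h = 60, λ = 250 bp — narrow enough to classify as
point after convolution, tall enough to clear the tenfold threshold),
2×10⁵ IP reads and a deep 4×10⁶-read input. The deep input keeps the
input track's sampling noise from dominating peak-boundary variance at
this IP depth; at equal depths the tenfold crossing position fluctuates
by several hundred bp, which is visible in the spreading-width
comparisons.

*Transposon libraries.* Insertions are restricted to TA dinucleotides
(the defining target preference of mariner-family transposons). Control
clones insert uniformly over TA sites; test clones are weighted
`fitness_in` inside the planted zone and `fitness_out` outside.
Per-clone read counts are 1 + negative binomial with configurable mean
(default 20) and shape (default 2), giving the over-dispersion of
amplified libraries. Zone-recovery reference conditions: 2 Mb genome
(a desk-scale stand-in for a multi-Mb chromosome that keeps the 650 kb
zone a minority of bins), planted zone (−200 kb, +450 kb), 4-fold
selection, 10⁴ clones, 50 seeded replicates.

*Foci tables.* Each nucleate cell draws a stage: both channels single
(probability 0.4), one channel duplicated (0.3; the parS-proximal
channel is the duplicated one with probability `q_first`, default 0.8),
or both duplicated (0.3). Duplicated channels place one focus near each
of the bipolar means (default 0.2/0.8, sd 0.05, clipped to [0, 1]);
single-focus channels sit near mid-cell. Each focus is detected
independently with `detection_prob`; anucleate cells (planted fraction)
carry no foci.

What the generators do **not** emulate: replication-gradient (marker
frequency) coverage bias, sequencing errors, PCR duplicate structure,
chromatin accessibility artifacts, cell-cycle stage mixtures and
segmentation errors. Passing recovery tests therefore demonstrates the
correctness of the statistics under the stated models, not robustness to
every artifact of real libraries.

## Numerical choices and degenerate inputs

Pseudocounts as above; enrichment requires positive totals and equal
track lengths; thresholds must exceed 1 (fold) or are free (log2).
Collapsing ties break toward the plus strand then lowest start. Peak and
zone runs touching both ends of the linear representation are joined
once circularly. `boxplot_stats` rejects empty input; `detect_zone`
returns an empty zone rather than raising. Zone bin-edge offsets assume
the genome length is a multiple of the bin size for exact labels;
otherwise the final short bin's edges are approximate by up to the
shortfall.

## Known limitations

- Single-contig circular genomes only; no multi-replicon support.
- The exponential spreading shape is a modeling convenience, not a
  mechanistic claim.
- Zone boundaries from real libraries depend on the declared threshold
  rule; the defaults are stated, not inferred from any figure.
- Wild-type isolates can differ structurally from public reference
  assemblies (insertions, deletions, rRNA-operon inversions), shifting
  coordinates by kilobases in places; offsets against a public reference
  should be interpreted with that in mind.
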