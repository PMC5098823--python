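"""Tn-seq competence-zone statistic: binned log2 library ratios.

Two mariner transposon libraries are compared: a test library whose
transposon carries a *parS* site and a control library without one, both
delivered into a strain lacking the native parS sites.  Clones whose
insertion places parS where it can support chromosome segregation gain a
growth advantage, so insertions accumulate there in the test library.
The statistic is, per 10 kb bin, the log2 ratio of insertion read counts
normalized to each library's total; the "competence zone" is the maximal
contiguous super-threshold run of bins around oriC.

Bins are anchored at oriC (edges at oriC + k * bin_bp on the circle) so
zone boundaries read directly as signed oriC offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_coords import GenomeSequence, to_ori_offset

DEFAULT_BIN_BP = 10_000
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ZONE_THRESHOLD = 1.0   # log2 units
DEFAULT_MIN_RUN_BINS = 3


@dataclass
class InsertionTable:
    """Per-site transposon insertion read tallies for one library."""

    site_counts: dict[int, int]
    total_reads: int
    library: str = "control"

    @property
    def n_sites(self) -> int:
        return len(self.site_counts)


@dataclass
class BinRatioTrack:
    """Per-bin log2 ratio of normalized insertion counts (test / control)."""

    log2_ratio: np.ndarray
    bin_bp: int
    oric: int
    genome_length: int

    @property
    def n_bins(self) -> int:
        return len(self.log2_ratio)

    def bin_midpoint_offsets(self) -> np.ndarray:
        """Signed oriC offset of each bin midpoint (bins indexed from oriC)."""
        L, b = self.genome_length, self.bin_bp
        mids = (np.arange(self.n_bins) * b + b / 2) % L
        return np.where(mids * 2 > L, mids - L, mids)


@dataclass
class CompetenceZone:
    left: int | None      # signed oriC offset of the outer left bin edge
    right: int | None     # signed oriC offset of the outer right bin edge
    threshold: float = DEFAULT_ZONE_THRESHOLD
    covers_oriC: bool = False
    n_bins: int = 0

    @property
    def empty(self) -> bool:
        return self.left is None

    @property
    def width_bp(self) -> int:
        return 0 if self.empty else self.right - self.left


def tally_insertions(positions, genome: GenomeSequence, library: str = "control") -> InsertionTable:
    """Exact per-site read tallies from mapped insertion positions."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("no insertion positions supplied")
    L = len(genome)
    if np.any((positions < 0) | (positions >= L)):
        raise ValueError("insertion position outside the genome")
    sites, counts = np.unique(positions, return_counts=True)
    return InsertionTable(
        site_counts={int(s): int(c) for s, c in zip(sites, counts)},
        total_reads=int(counts.sum()),
        library=library,
    )


def _bin_totals(table: InsertionTable, genome: GenomeSequence, bin_bp: int,
                distinct_sites: bool) -> np.ndarray:
    L = len(genome)
    n_bins = -(-L // bin_bp)  # ceil
    totals = np.zeros(n_bins, dtype=float)
    for pos, count in table.site_counts.items():
        b = ((pos - genome.oric) % L) // bin_bp
        totals[b] += 1 if distinct_sites else count
    return totals


def bin_log2_ratio(pars: InsertionTable, ctrl: InsertionTable, genome: GenomeSequence,
                   bin_bp: int = DEFAULT_BIN_BP, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   distinct_sites: bool = False) -> BinRatioTrack:
    """Per-bin log2 of the normalized test/control insertion-count ratio.

    r(b) = log2( ((n_parS(b)+eps)/N_parS) / ((n_ctrl(b)+eps)/N_ctrl) ).
    ``distinct_sites`` switches the per-bin numerators from read counts to
    distinct insertion sites (totals switch accordingly).
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    n_test = _bin_totals(pars, genome, bin_bp, distinct_sites)
    n_ctrl = _bin_totals(ctrl, genome, bin_bp, distinct_sites)
    tot_test = n_test.sum() if distinct_sites else pars.total_reads
    tot_ctrl = n_ctrl.sum() if distinct_sites else ctrl.total_reads
    if tot_test <= 0 or tot_ctrl <= 0:
        raise ValueError("both libraries need positive totals")
    r = np.log2(((n_test + pseudocount) / tot_test) / ((n_ctrl + pseudocount) / tot_ctrl))
    return BinRatioTrack(log2_ratio=r, bin_bp=bin_bp, oric=genome.oric, genome_length=len(genome))


def detect_zone(track: BinRatioTrack, threshold: float = DEFAULT_ZONE_THRESHOLD,
                min_run_bins: int = DEFAULT_MIN_RUN_BINS,
                merge_gap_bins: int = 0) -> CompetenceZone:
    """Maximal super-threshold run of bins containing, or nearest to, oriC.

    Bins are indexed from oriC, so oriC sits at the shared edge of the
    first and last bin; a run spanning that edge "covers" oriC.  Runs
    separated by at most ``merge_gap_bins`` sub-threshold bins are bridged
    (useful for sparse libraries where single bins dip by chance); runs
    shorter than ``min_run_bins`` are then ignored.  With no qualifying
    run the result is an empty zone, not an exception.
    """
    r = track.log2_ratio
    nb = len(r)
    above = r >= threshold
    if not above.any():
        return CompetenceZone(left=None, right=None, threshold=threshold)
    if above.all():
        runs = [(0, nb)]
    else:
        # rotate so the scan starts in a below-threshold bin, then unrotate
        start0 = int(np.flatnonzero(~above)[0])
        rot = np.roll(above, -start0)
        edges = np.flatnonzero(np.diff(rot.astype(np.int8)))
        starts = [e + 1 for e in edges if not rot[e]]
        ends = [e + 1 for e in edges if rot[e]]
        if rot[-1]:
            ends.append(nb)
        runs = [((s + start0) % nb, (e + start0 - 1) % nb + 1) for s, e in zip(starts, ends)]
        runs = [(s, e if e > s else e + nb) for s, e in runs]
    if merge_gap_bins > 0 and len(runs) > 1:
        runs.sort()
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= merge_gap_bins:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        if len(merged) > 1 and (merged[0][0] + nb) - merged[-1][1] <= merge_gap_bins:
            sl, _ = merged.pop()
            _, e0 = merged.pop(0)
            merged.append((sl, e0 + nb))
        runs = merged
    runs = [(s, e) for s, e in runs if e - s >= min_run_bins]
    if not runs:
        return CompetenceZone(left=None, right=None, threshold=threshold)

    def distance_to_oric(run: tuple[int, int]) -> int:
        s, e = run
        # oriC lies at bin-edge 0 (== nb); run covers it if it includes bin 0 or wraps
        if s == 0 or e >= nb:
            return 0
        return min(s, nb - e)

    s, e = min(runs, key=distance_to_oric)
    L, b = track.genome_length, track.bin_bp

    def signed(edge_bins: int) -> int:
        d = (edge_bins * b) % L
        return d - L if d * 2 > L else d

    left, right = signed(s), signed(e)
    if right <= left:
        right += L
    covers = left <= 0 <= right
    return CompetenceZone(left=int(left), right=int(right), threshold=threshold,
                         covers_oriC=bool(covers), n_bins=e - s)


def ta_sites(genome: GenomeSequence) -> np.ndarray:
    """0-based positions i with seq[i:i+2] == 'TA', wrapping if circular."""
    seq = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)
    t, a = ord("T"), ord("A")
    hits = np.flatnonzero((seq[:-1] == t) & (seq[1:] == a))
    if genome.circular and len(genome) >= 2 and genome.seq[-1] == "T" and genome.seq[0] == "A":
        hits = np.append(hits, len(genome) - 1)
    return hits.astype(np.int64)


def write_ratio_bedgraph(track: BinRatioTrack, path) -> None:
    """log2 ratios as bedGraph over oriC-anchored bins (linear coordinates)."""
    L, b, oric = track.genome_length, track.bin_bp, track.oric
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="tnseq_log2_ratio"\n')
        for k, val in enumerate(track.log2_ratio):
            s = (oric + k * b) % L
            e = min(s + b, L)
            fh.write(f"genome\t{s}\t{e}\t{val:.6g}\n")
            if s + b > L:  # bin wraps the linear origin
                fh.write(f"genome\t0\t{(s + b) % L}\t{val:.6g}\n")
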