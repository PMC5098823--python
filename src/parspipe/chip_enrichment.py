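"""ChIP-seq enrichment: coverage, smoothing, IP/input fold ratio, peaks.

The statistic follows the classical input-normalized design for bacterial
ChIP-seq: per-base fragment coverage for the immunoprecipitated (IP) and
input (IN) fractions is smoothed over a 200 bp window (the approximate
size of the sonicated fragments), each track is normalized to its total
read count, and the per-base enrichment fold is the ratio of the two
normalized tracks.  Peaks are maximal contiguous runs above a fold
threshold (10 by default); ParB "spreading" around a parS site shows up
as a super-threshold region many kilobases wide, while secondary binding
sites give narrow point peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .genome_coords import GenomeSequence, to_ori_offset
from .motif_scan import MotifHit

DEFAULT_WINDOW_BP = 200
DEFAULT_THRESHOLD = 10.0
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FRAGMENT_LENGTH = 500
DEFAULT_SPREAD_MIN_BP = 2000


@dataclass
class CoverageTrack:
    counts: np.ndarray          # per-base fragment-overlap counts, length L
    total_reads: int
    label: str = "IP"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")


@dataclass
class EnrichmentProfile:
    fold: np.ndarray
    window_bp: int = DEFAULT_WINDOW_BP
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class Peak:
    """Maximal contiguous region with fold >= threshold.

    ``end`` may exceed the genome length for a peak wrapping across the
    origin; its width is always ``end - start``.
    """

    start: int
    end: int
    max_fold: float
    mean_fold: float
    contains_parS: bool = False
    classification: str = ""
    ori_offset: int | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


def coverage_from_reads(reads, genome_length: int, fragment_length: int | None = None,
                        label: str = "IP", circular: bool = True) -> CoverageTrack:
    """Per-base fragment coverage from read intervals or 5' positions.

    ``reads`` is either an (n, 2) array of [start, end) intervals or, when
    ``fragment_length`` is given, an (n, 2) array of (5' position, strand
    sign +1/-1) pairs extended to the fragment length in the read
    direction.  Intervals wrap circularly.
    """
    reads = np.asarray(reads)
    if reads.size == 0:
        raise ValueError("no reads supplied; an empty track cannot be normalized")
    if reads.ndim != 2 or reads.shape[1] != 2:
        raise ValueError("reads must be an (n, 2) array")

    if fragment_length is not None:
        pos, strand = reads[:, 0].astype(np.int64), reads[:, 1].astype(np.int64)
        starts = np.where(strand >= 0, pos, pos - fragment_length + 1)
        widths = np.full(len(starts), fragment_length, dtype=np.int64)
    else:
        starts = reads[:, 0].astype(np.int64)
        widths = reads[:, 1].astype(np.int64) - starts
    if np.any(widths <= 0):
        raise ValueError("empty or negative-length read intervals")

    L = genome_length
    if np.any(widths > L):
        raise ValueError("read interval longer than the genome")
    starts = starts % L
    ends = starts + widths
    if not circular and np.any(ends > L):
        raise ValueError("read interval beyond linear genome end")

    diff = np.zeros(L, dtype=float)
    np.add.at(diff, starts, 1.0)
    nonwrap = ends < L
    np.add.at(diff, ends[nonwrap], -1.0)
    wrapped = ends > L  # a read ending exactly at L needs no tail
    if np.any(wrapped):
        diff[0] += int(wrapped.sum())
        np.add.at(diff, ends[wrapped] % L, -1.0)
    counts = np.cumsum(diff)
    return CoverageTrack(counts=counts, total_reads=len(starts), label=label)


def smooth(track: CoverageTrack, window_bp: int = DEFAULT_WINDOW_BP) -> CoverageTrack:
    """Centered circular moving average; even windows are bumped to odd.

    The mean filter preserves total mass under circular wrap, so the
    normalization downstream is unaffected.
    """
    L = len(track.counts)
    if window_bp > L:
        raise ValueError(f"smoothing window {window_bp} exceeds track length {L}")
    if window_bp % 2 == 0:
        window_bp += 1
    smoothed = uniform_filter1d(track.counts, size=window_bp, mode="wrap")
    return CoverageTrack(counts=smoothed, total_reads=track.total_reads, label=track.label)


def enrichment(ip: CoverageTrack, input_: CoverageTrack,
               window_bp: int = DEFAULT_WINDOW_BP,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> EnrichmentProfile:
    """Smoothed, total-read-normalized IP/input fold ratio per base.

    fold[i] = ((ip[i] + eps) / N_ip) / ((in[i] + eps) / N_in), with both
    tracks smoothed first.  The pseudocount keeps the ratio finite at
    zero-input bases and is symmetric in depth.
    """
    if len(ip.counts) != len(input_.counts):
        raise ValueError("IP and input tracks have different lengths")
    if ip.total_reads <= 0 or input_.total_reads <= 0:
        raise ValueError("both tracks need a positive total read count")
    ip_s = smooth(ip, window_bp).counts
    in_s = smooth(input_, window_bp).counts
    fold = ((ip_s + pseudocount) / ip.total_reads) / ((in_s + pseudocount) / input_.total_reads)
    return EnrichmentProfile(fold=fold, window_bp=window_bp, pseudocount=pseudocount)


def _runs_above(fold: np.ndarray, threshold: float, circular: bool) -> list[tuple[int, int]]:
    """Maximal [start, end) runs with fold >= threshold; a run crossing the
    origin is reported once with end > L."""
    above = fold >= threshold
    L = len(fold)
    if not above.any():
        return []
    if above.all():
        return [(0, L)]
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) + 1 for e in edges if above[e]]
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(L)
    runs = list(zip(starts, ends))
    if circular and above[0] and above[-1] and len(runs) > 1:
        (s_last, _) = runs[-1]
        (_, e_first) = runs[0]
        runs = runs[1:-1] + [(s_last, L + e_first)]
    return sorted(runs)


def call_peaks(profile: EnrichmentProfile, threshold: float = DEFAULT_THRESHOLD,
               min_width_bp: int = 1, merge_gap_bp: int = 0,
               genome: GenomeSequence | None = None,
               circular: bool = True) -> list[Peak]:
    """Maximal runs of fold >= threshold, optionally merged and filtered.

    Runs separated by a gap smaller than ``merge_gap_bp`` are merged; runs
    narrower than ``min_width_bp`` are dropped.  Peaks are sorted by
    descending max fold (the "most abundant regions first" convention).
    """
    if threshold <= 1:
        raise ValueError("enrichment threshold must exceed 1")
    fold = profile.fold
    L = len(fold)
    runs = _runs_above(fold, threshold, circular)
    if merge_gap_bp > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe < merge_gap_bp:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        # circular closure between last and first run
        if circular and len(merged) > 1:
            s0, e0 = merged[0]
            sl, el = merged[-1]
            if (s0 + L) - el < merge_gap_bp:
                merged = merged[1:-1] + [(sl, e0 + L)]
        runs = merged

    peaks = []
    for s, e in runs:
        if e - s < min_width_bp:
            continue
        idx = np.arange(s, e) % L
        seg = fold[idx]
        mid = (s + (e - s) // 2) % L
        peaks.append(
            Peak(start=s, end=e, max_fold=float(seg.max()), mean_fold=float(seg.mean()),
                 ori_offset=to_ori_offset(mid, genome) if genome is not None else None)
        )
    peaks.sort(key=lambda p: -p.max_fold)
    return peaks


@dataclass
class SpreadingResult:
    anchor: int
    width_bp: int
    region: tuple[int, int] | None  # [start, end) of the containing run


def spreading_extent(profile: EnrichmentProfile, anchors, threshold: float = DEFAULT_THRESHOLD,
                     circular: bool = True) -> list[SpreadingResult]:
    """Width of the maximal super-threshold region containing each anchor.

    Anchors falling in sub-threshold territory get width 0 with a warning;
    anchors sharing one region report that region's single width.
    """
    fold = profile.fold
    L = len(fold)
    runs = _runs_above(fold, threshold, circular)
    results = []
    for anchor in anchors:
        a = anchor % L
        region = None
        for s, e in runs:
            if s <= a < e or (e > L and a < e - L):
                region = (s, e)
                break
        if region is None:
            warnings.warn(f"anchor {anchor} lies in a sub-threshold region; width 0")
            results.append(SpreadingResult(anchor=anchor, width_bp=0, region=None))
        else:
            results.append(SpreadingResult(anchor=anchor, width_bp=region[1] - region[0],
                                           region=region))
    return results


def annotate_peaks(peaks: list[Peak], hits: list[MotifHit],
                   spread_min_bp: int = DEFAULT_SPREAD_MIN_BP,
                   genome_length: int | None = None) -> list[Peak]:
    """Flag parS content and classify each peak as spreading or point.

    A peak "contains parS" when any hit footprint overlaps it; it is a
    spreading peak when its width reaches ``spread_min_bp``, otherwise a
    point (secondary-site-like) peak.
    """
    for p in peaks:
        contains = False
        for h in hits:
            hs, he = h.start, h.end
            if hs < p.end and p.start < he:
                contains = True
            elif genome_length is not None:
                L = genome_length
                for shift in (-L, L):
                    if hs + shift < p.end and p.start < he + shift:
                        contains = True
        p.contains_parS = contains
        p.classification = "spreading" if p.width >= spread_min_bp else "point"
    return peaks


def write_bedgraph(values: np.ndarray, path, name: str = "enrichment") -> None:
    """Write a per-base track as bedGraph, merging equal-valued runs."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(values)]))
        for s, e in zip(starts, ends):
            fh.write(f"genome\t{s}\t{e}\t{values[s]:.6g}\n")


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    """Peak table with 1-based inclusive text coordinates and annotations."""
    with open(path, "w") as fh:
        fh.write("start_1based\tend\twidth_bp\tmax_fold\tmean_fold\t"
                 "ori_offset\tcontains_parS\tclassification\n")
        for p in peaks:
            fh.write(f"{p.start + 1}\t{p.end}\t{p.width}\t{p.max_fold:.3f}\t"
                     f"{p.mean_fold:.3f}\t{p.ori_offset if p.ori_offset is not None else ''}\t"
                     f"{int(p.contains_parS)}\t{p.classification}\n")
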