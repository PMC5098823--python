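"""Mismatch-tolerant scanning for degenerate DNA motifs on a circular genome.

The *parS* centromere consensus in *Pseudomonas aeruginosa* is the
near-palindromic 16-mer ``TGTTCCACGTGGAACM`` (IUPAC M = A or C).  Because
the reverse complement of one resolution of the consensus matches the
other resolution within one mismatch, strand-level hits at k >= 1 would
double-count every site; occurrences are therefore counted at the *locus*
level by collapsing overlapping hits (see :func:`collapse_loci`).

Degeneracy is asymmetric by design: IUPAC codes are honoured in the
pattern only, and ``N`` in the genome matches nothing, so counts are
conservative and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_coords import GenomeSequence, to_ori_offset

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# genome base -> integer code; N = 4 matches no pattern letter
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    """One motif occurrence.

    ``end = start + len(pattern)`` and may exceed the genome length for a
    hit wrapping across the origin of the linear representation.
    ``matched_seq`` is the genome slice, reverse-complemented for minus-
    strand hits so it reads in pattern orientation.
    """

    start: int
    end: int
    strand: str
    mismatches: int
    matched_seq: str
    ori_offset: int


def _encode(seq: str) -> np.ndarray:
    codes = np.full(256, 4, dtype=np.uint8)
    for b, c in _BASE_CODE.items():
        codes[ord(b)] = c
    return codes[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pattern_table(pattern: str) -> np.ndarray:
    """(m, 5) boolean table: table[j, code] = does genome code match pattern[j]."""
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, letter in enumerate(pattern):
        for base in IUPAC[letter]:
            table[j, _BASE_CODE[base]] = True
    return table  # column 4 (N) stays all-False: N matches nothing


def _mismatch_counts(codes_ext: np.ndarray, table: np.ndarray, n_windows: int) -> np.ndarray:
    m = table.shape[0]
    mm = np.zeros(n_windows, dtype=np.int32)
    for j in range(m):
        mm += ~table[j][codes_ext[j : j + n_windows]]
    return mm


def scan(genome: GenomeSequence, pattern: str, max_mismatches: int = 0) -> list[MotifHit]:
    """All windows on both strands within ``max_mismatches`` of the pattern.

    Windows wrap across the origin when the genome is circular.  Hits are
    sorted by start position.
    """
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)!r}")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    L, m = len(genome), len(pattern)
    if m > L:
        raise ValueError(f"pattern length {m} exceeds genome length {L}")

    seq = genome.seq + (genome.seq[: m - 1] if genome.circular and m > 1 else "")
    codes = _encode(seq)
    n_windows = L if genome.circular else L - m + 1

    hits: list[MotifHit] = []
    for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
        mm = _mismatch_counts(codes, _pattern_table(pat), n_windows)
        for start in np.flatnonzero(mm <= max_mismatches):
            start = int(start)
            window = seq[start : start + m]
            hits.append(
                MotifHit(
                    start=start,
                    end=start + m,
                    strand=strand,
                    mismatches=int(mm[start]),
                    matched_seq=window if strand == "+" else reverse_complement(window),
                    ori_offset=to_ori_offset(start, genome),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def collapse_loci(hits: list[MotifHit], genome_length: int | None = None) -> list[MotifHit]:
    """Merge hits with overlapping genomic footprints into single loci.

    Each locus is represented by its best hit: fewest mismatches, ties
    broken toward the plus strand, then the lowest start.  Footprint
    overlap is evaluated on the circle when ``genome_length`` is given.
    """
    if not hits:
        return []

    def footprint(h: MotifHit) -> tuple[int, int]:
        return h.start, h.end

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        if a[0] < b[1] and b[0] < a[1]:
            return True
        if genome_length is None:
            return False
        L = genome_length
        # compare wrapped copies shifted by one genome length
        for shift in (-L, L):
            if a[0] + shift < b[1] and b[0] < a[1] + shift:
                return True
        return False

    order = sorted(hits, key=lambda h: h.start)
    clusters: list[list[MotifHit]] = []
    for h in order:
        placed = False
        for cluster in clusters:
            if any(overlaps(footprint(h), footprint(c)) for c in cluster):
                cluster.append(h)
                placed = True
                break
        if not placed:
            clusters.append([h])

    def best(cluster: list[MotifHit]) -> MotifHit:
        return min(cluster, key=lambda h: (h.mismatches, h.strand != "+", h.start))

    loci = [best(c) for c in clusters]
    loci.sort(key=lambda h: h.start)
    return loci


def write_hits_bed(hits: list[MotifHit], path, genome_length: int | None = None,
                   pattern_length: int = 16) -> None:
    """Write hits as BED6 lines; score = pattern length minus mismatches.

    A hit wrapping across the origin is split into two lines tiling its
    footprint, flagged by a shared name.
    """
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            score = max(len(h.matched_seq), pattern_length) - h.mismatches
            name = f"hit{i}"
            if genome_length is not None and h.end > genome_length:
                L = genome_length
                fh.write(f"genome\t{h.start}\t{L}\t{name}_wrap\t{score}\t{h.strand}\n")
                fh.write(f"genome\t0\t{h.end - L}\t{name}_wrap\t{score}\t{h.strand}\n")
            else:
                fh.write(f"genome\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}\n")
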