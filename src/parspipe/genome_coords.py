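"""Genome I/O and the circular, oriC-anchored coordinate system.

Bacterial chromosomes are circular and replicate bidirectionally from a
single origin, *oriC*.  Positions are therefore most naturally reported as
signed distances from oriC: positive offsets run along one replichore
(increasing linear coordinate by default), negative offsets along the
other.  Every downstream module (motif scanning, ChIP enrichment, Tn-seq
binning) reports coordinates through this system.

Internally all coordinates are 0-based, half-open.  Signed offsets live in
the band ``(-L/2, L/2]`` so that each linear position has exactly one
offset and the mapping is a bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """A single circular (or linear) chromosome with an oriC anchor.

    Parameters
    ----------
    name:
        Record label (FASTA header).
    seq:
        Uppercase DNA over ``{A, C, G, T, N}``.
    circular:
        Whether coordinates wrap across the sequence end.
    oric:
        0-based linear position of the replication origin.
    """

    name: str
    seq: str
    circular: bool = True
    oric: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - GENOME_ALPHABET
        if bad:
            raise ValueError(
                f"genome contains non-ACGTN characters: {sorted(bad)!r}"
            )
        if not self.seq:
            raise ValueError("empty genome sequence")
        if not 0 <= self.oric < len(self.seq):
            raise ValueError(
                f"oriC position {self.oric} outside genome of length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``, wrapping past the end if circular."""
        L = len(self.seq)
        if end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(f"slice [{start}, {end}) beyond linear genome of length {L}")
        return self.seq[start:] + self.seq[: end - L]


def to_ori_offset(pos: int, genome: GenomeSequence, flip_replichores: bool = False) -> int:
    """Signed oriC-relative offset of a linear position, in ``(-L/2, L/2]``.

    Positive offsets increase with the linear coordinate (the "right
    replichore" by convention); ``flip_replichores`` negates the sign.
    """
    L = len(genome)
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} outside [0, {L})")
    off = (pos - genome.oric) % L
    if off * 2 > L:
        off -= L
    if flip_replichores:
        off = -off
        if off * 2 <= -L:  # keep the band half-open on the negative side
            off += L
    return off


def from_ori_offset(offset: int, genome: GenomeSequence, flip_replichores: bool = False) -> int:
    """Inverse of :func:`to_ori_offset`: linear position of a signed offset."""
    L = len(genome)
    if flip_replichores:
        offset = -offset
    return (genome.oric + offset) % L


def circular_distance(a: int, b: int, length: int) -> int:
    """Shorter-arc distance between two positions on a circle of given length."""
    d = abs(a - b) % length
    return min(d, length - d)


def read_fasta(path, circular: bool = True, oric: int = 0) -> GenomeSequence:
    """Read a single-record FASTA into a :class:`GenomeSequence`.

    ``U`` (RNA) and any other non-ACGTN letters are rejected; multi-record
    files raise with the record count.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"expected a single-record FASTA, found {len(records)} records in {path}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if "U" in seq:
        raise ValueError("RNA alphabet (U) not accepted; supply a DNA FASTA")
    return GenomeSequence(name=rec.id, seq=seq, circular=circular, oric=oric)


def write_fasta(genome: GenomeSequence, path) -> None:
    """Write a genome as single-record FASTA, 80 columns per line."""
    rec = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")
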