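"""Seeded generators with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed, and each
returns (or writes) a machine-readable truth record so downstream
recovery tests can compare estimates against what was planted.

The generators emulate the *signatures* the pipeline measures, not the
underlying biophysics:

* genomes — i.i.d. bases at a chosen GC with motifs planted verbatim;
* ChIP read sets — uniform input, IP fragment density elevated around
  anchor sites with an exponential decay ("spreading" of width ~lambda
  for nucleation-spread sites, a few hundred bp for point sites);
* mariner transposon libraries — insertions restricted to TA
  dinucleotides, with a positional fitness weight over a contiguous
  oriC-spanning zone and over-dispersed per-clone read counts;
* foci tables — two-channel bipolar focus positions near 0.2/0.8
  relative cell length with configurable spread, detection dropout, an
  anucleate-cell fraction, and a "duplicates first" probability for the
  parS-proximal channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d

from .genome_coords import GenomeSequence
from .motif_scan import IUPAC, reverse_complement
from .foci_stats import CellRecord
from .tnseq_zone import InsertionTable, ta_sites


# --- genomes ---------------------------------------------------------------

def gen_genome(length: int, gc: float = 0.5, planted=None, seed: int = 0,
               name: str = "synthetic", oric: int = 0) -> tuple[GenomeSequence, list[dict]]:
    """Random genome with motifs planted verbatim at given positions.

    ``planted`` is a list of (pattern, position, strand) triples; IUPAC
    degeneracies in a pattern are resolved uniformly at random (recorded
    in the truth list).  Overlapping footprints raise.

    Returns (genome, truth) where truth is a list of dicts with the
    planted pattern, resolved sequence, position and strand.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=p)

    truth = []
    occupied: list[tuple[int, int]] = []
    for pattern, position, strand in (planted or []):
        m = len(pattern)
        end = position + m
        if end > length:
            raise ValueError(f"planted motif at {position} extends past genome end")
        for s, e in occupied:
            if position < e and s < end:
                raise ValueError(f"planted footprints overlap at {position}")
        occupied.append((position, end))
        resolved = "".join(rng.choice(list(IUPAC[c])) for c in pattern.upper())
        inserted = resolved if strand == "+" else reverse_complement(resolved)
        seq[position:end] = list(inserted)
        truth.append({"pattern": pattern, "resolved": resolved,
                      "start": position, "end": end, "strand": strand})
    genome = GenomeSequence(name=name, seq="".join(seq), circular=True, oric=oric)
    return genome, truth


def write_truth_json(truth, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump({"params": params or {}, "truth": truth}, fh, indent=1, default=str)


# --- ChIP reads ------------------------------------------------------------

@dataclass
class SpreadingSite:
    """One enrichment anchor: peak fold over background and decay scale."""
    position: int
    peak_fold: float = 30.0
    decay_scale: float = 4000.0  # bp


@dataclass
class SpreadingModel:
    """IP fragment-density model: uniform background plus per-anchor
    exponentially decaying elevation."""
    sites: list[SpreadingSite]
    fragment_length: int = 500
    background: float = 1.0


def _site_weight(length: int, model: SpreadingModel) -> np.ndarray:
    """Un-normalized fragment-midpoint density over the genome."""
    x = np.arange(length)
    w = np.full(length, model.background, dtype=float)
    for site in model.sites:
        d = np.abs(x - site.position)
        d = np.minimum(d, length - d)
        w += model.background * (site.peak_fold - 1.0) * np.exp(-d / site.decay_scale)
    return w


def gen_chip_reads(genome: GenomeSequence, model: SpreadingModel,
                   n_ip: int, n_in: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """IP and input fragment interval sets, as (n, 2) [start, end) arrays.

    Input fragments are uniform.  IP fragment *midpoints* are drawn from
    the model density, so expected coverage peaks at each anchor.
    """
    if n_ip <= 0 or n_in <= 0:
        raise ValueError("read counts must be positive")
    rng = np.random.default_rng(seed)
    L, F = len(genome), model.fragment_length
    w = _site_weight(L, model)
    mids_ip = rng.choice(L, size=n_ip, p=w / w.sum())
    starts_ip = (mids_ip - F // 2) % L
    starts_in = rng.integers(0, L, size=n_in)
    ip = np.column_stack([starts_ip, starts_ip + F])
    inp = np.column_stack([starts_in, starts_in + F])
    return ip, inp


def expected_fold_profile(genome_length: int, model: SpreadingModel,
                          window_bp: int = 200) -> np.ndarray:
    """Closed-form expectation of the pipeline's enrichment fold.

    The fragment-midpoint density is convolved with the fragment-coverage
    box and the smoothing box; the input expectation is uniform, so the
    expected fold is the doubly box-filtered weight relative to its
    genome-wide mean.  This is the truth that simulation-recovery tests
    compare against (the raw per-anchor peak fold is attenuated by both
    convolutions and by total-read normalization).
    """
    w = _site_weight(genome_length, model)
    cov = uniform_filter1d(w, size=model.fragment_length, mode="wrap")
    if window_bp % 2 == 0:
        window_bp += 1
    cov = uniform_filter1d(cov, size=window_bp, mode="wrap")
    return cov / cov.mean()


# --- transposon libraries --------------------------------------------------

@dataclass
class SelectionModel:
    """Positional fitness for parS-carrying clones: weight ``fitness_in``
    for insertions whose oriC offset falls in [zone_left, zone_right),
    ``fitness_out`` elsewhere."""
    zone_left: int     # signed oriC offsets, bp
    zone_right: int
    fitness_in: float = 4.0
    fitness_out: float = 1.0


def gen_tn_libraries(genome: GenomeSequence, model: SelectionModel,
                     n_clones: int = 10_000, reads_per_clone_mean: float = 20.0,
                     dispersion: float = 2.0, seed: int = 0
                     ) -> tuple[InsertionTable, InsertionTable]:
    """Paired mariner libraries: (parS test library, control library).

    Insertions hit TA dinucleotides only.  Control clones insert
    uniformly over TA sites; test clones are weighted by the selection
    model.  Per-clone read counts follow a negative binomial with the
    stated mean (variance = mean * (1 + mean/dispersion) > mean).
    """
    if model.fitness_in <= 0 or model.fitness_out <= 0:
        raise ValueError("fitness weights must be positive")
    sites = ta_sites(genome)
    if sites.size == 0:
        raise ValueError("genome has no TA dinucleotide; mariner cannot insert")
    rng = np.random.default_rng(seed)
    L, oric = len(genome), genome.oric

    off = (sites - oric) % L
    off = np.where(off * 2 > L, off - L, off)
    in_zone = (off >= model.zone_left) & (off < model.zone_right)
    w = np.where(in_zone, model.fitness_in, model.fitness_out).astype(float)

    def library(weights, label: str) -> InsertionTable:
        clone_sites = rng.choice(sites, size=n_clones, p=weights / weights.sum())
        # NB(mean mu, shape k): variance mu + mu^2/k; at least 1 read per clone
        reads = 1 + rng.negative_binomial(
            dispersion, dispersion / (dispersion + reads_per_clone_mean - 1), size=n_clones
        )
        counts: dict[int, int] = {}
        for s, r in zip(clone_sites, reads):
            counts[int(s)] = counts.get(int(s), 0) + int(r)
        return InsertionTable(site_counts=counts, total_reads=int(reads.sum()), library=label)

    test = library(w, "parS")
    ctrl = library(np.ones_like(w), "control")
    return test, ctrl


# --- foci tables -----------------------------------------------------------

@dataclass
class FociModel:
    """Two-channel bipolar foci model.

    Channel A is the parS-proximal locus: in three-foci cells it is the
    duplicated (two-focus) channel with probability ``q_first``.  Cell
    stage probabilities: both loci single (p_single), exactly one
    duplicated (p_three), both duplicated (1 - p_single - p_three).
    """
    channels: tuple[str, str] = ("A", "B")
    means: tuple[float, float] = (0.2, 0.8)
    sd: float = 0.05
    detection_prob: float = 1.0
    anucleate_fraction: float = 0.0
    q_first: float = 0.8
    p_single: float = 0.4
    p_three: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.detection_prob, self.anucleate_fraction, self.q_first,
                  self.p_single, self.p_three):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_single + self.p_three > 1:
            raise ValueError("p_single + p_three must not exceed 1")
        for m in self.means:
            if not 0 <= m <= 1:
                raise ValueError("means must lie in [0, 1]")


def gen_foci_cells(model: FociModel, n_cells: int, seed: int = 0
                   ) -> tuple[list[CellRecord], dict]:
    """Per-cell foci table plus the realized truth counts.

    Single-focus channels place the focus near mid-cell; duplicated
    channels place one focus near each of the model means.  Positions are
    clipped to [0, 1]; each focus is independently detected with
    ``detection_prob``; anucleate cells carry no foci.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    a, b = model.channels
    cells: list[CellRecord] = []
    truth = {"n_anucleate": 0, "n_three_foci_a_first": 0, "n_three_foci_b_first": 0,
             "stage_counts": {"single": 0, "three": 0, "double": 0}}

    def draw(mean: float) -> float:
        return float(np.clip(rng.normal(mean, model.sd), 0.0, 1.0))

    for i in range(n_cells):
        cid = f"cell{i:05d}"
        if rng.random() < model.anucleate_fraction:
            truth["n_anucleate"] += 1
            cells.append(CellRecord(cid, 1.0, nucleoid_present=False, foci=[]))
            continue
        u = rng.random()
        foci: list[tuple[str, float]] = []
        if u < model.p_single:
            truth["stage_counts"]["single"] += 1
            n_foci = {a: 1, b: 1}
        elif u < model.p_single + model.p_three:
            truth["stage_counts"]["three"] += 1
            if rng.random() < model.q_first:
                n_foci = {a: 2, b: 1}
                truth["n_three_foci_a_first"] += 1
            else:
                n_foci = {a: 1, b: 2}
                truth["n_three_foci_b_first"] += 1
        else:
            truth["stage_counts"]["double"] += 1
            n_foci = {a: 2, b: 2}
        for ch, n in n_foci.items():
            positions = [draw(0.5)] if n == 1 else [draw(model.means[0]), draw(model.means[1])]
            for p in positions:
                if rng.random() < model.detection_prob:
                    foci.append((ch, p))
        cells.append(CellRecord(cid, 1.0, nucleoid_present=True, foci=foci))
    return cells, truth
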