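"""Statistics over per-cell fluorescent-foci tables.

Input is the tabular output of cell segmentation / spot detection: one
row per focus with the cell id, cell length, nucleoid flag, channel and
position along the cell axis normalized to [0, 1].  The statistics
implemented here summarize ParB/parS and chromosomal-tag positioning:

* relative positions after random or reference-channel orientation,
* interfocal distances in two-focus cells (bipolar ParB foci sit near
  0.2/0.8 relative cell length, hence a typical distance of 0.6),
* boxplot summaries with the 1.5 x IQR outlier rule,
* foci-count repartitions over two channels,
* the three-foci classification: in cells with 3 foci over two loci,
  which locus has already separated after replication,
* anucleate-cell fraction with a bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellRecord:
    cell_id: str
    length: float
    nucleoid_present: bool = True
    foci: list[tuple[str, float]] = field(default_factory=list)  # (channel, rel pos)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"cell {self.cell_id}: non-positive length")
        for ch, p in self.foci:
            if not 0 <= p <= 1:
                raise ValueError(f"cell {self.cell_id}: focus position {p} outside [0, 1]")

    def count(self, channel: str) -> int:
        return sum(1 for ch, _ in self.foci if ch == channel)

    def positions(self, channel: str) -> list[float]:
        return [p for ch, p in self.foci if ch == channel]


@dataclass
class BoxplotStats:
    median: float
    q25: float
    q75: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


@dataclass
class FociRepartition:
    counts: dict[tuple[int, int], int]        # (n in A, n in B) -> cells
    percentages: dict[tuple[int, int], float]  # among foci-containing cells
    no_focus_percent: float                    # among all cells
    n_cells: int
    n_with_foci: int


def orient_cells(cells: list[CellRecord], policy: str = "random",
                 reference_channel: str | None = None,
                 seed: int | None = None) -> tuple[list[CellRecord], list[str]]:
    """Orient each cell's axis; returns (oriented cells, excluded cell ids).

    ``random`` flips each cell with probability 1/2 under the seed.
    ``by_reference`` flips so the reference channel's (first) focus lies
    nearer position 0; cells lacking a reference focus are excluded and
    reported.
    """
    rng = np.random.default_rng(seed)
    oriented: list[CellRecord] = []
    excluded: list[str] = []

    def flipped(cell: CellRecord) -> CellRecord:
        return CellRecord(cell.cell_id, cell.length, cell.nucleoid_present,
                          [(ch, 1.0 - p) for ch, p in cell.foci])

    for cell in cells:
        if policy == "random":
            oriented.append(flipped(cell) if rng.random() < 0.5 else cell)
        elif policy == "by_reference":
            if reference_channel is None:
                raise ValueError("by_reference policy needs a reference_channel")
            ref = cell.positions(reference_channel)
            if not ref:
                excluded.append(cell.cell_id)
                continue
            oriented.append(flipped(cell) if ref[0] > 0.5 else cell)
        else:
            raise ValueError(f"unknown orientation policy {policy!r}")
    return oriented, excluded


def interfocal_distance(cells: list[CellRecord], channel: str) -> tuple[np.ndarray, int]:
    """|p1 - p2| for cells with exactly two foci in the channel.

    Orientation-invariant.  Cells with any other focus count are skipped;
    the number skipped is returned alongside the distances.
    """
    distances, skipped = [], 0
    for cell in cells:
        pos = cell.positions(channel)
        if len(pos) == 2:
            distances.append(abs(pos[0] - pos[1]))
        else:
            skipped += 1
    return np.asarray(distances), skipped


def boxplot_stats(values) -> BoxplotStats:
    """Median, quartiles and the 1.5 x IQR outlier rule.

    Outliers are points 1.5 x IQR or more above the 75th percentile or
    below the 25th; whiskers reach the most extreme non-outlier points.
    Quartiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    is_out = (values >= q75 + 1.5 * iqr) & (values > q75) | \
             (values <= q25 - 1.5 * iqr) & (values < q25)
    inliers = values[~is_out]
    return BoxplotStats(
        median=float(med), q25=float(q25), q75=float(q75), iqr=float(iqr),
        whisker_low=float(inliers.min()), whisker_high=float(inliers.max()),
        outliers=np.sort(values[is_out]), n=values.size,
    )


def foci_repartition(cells: list[CellRecord], channel_a: str, channel_b: str) -> FociRepartition:
    """Foci-count categories (n_A, n_B) with percentages among foci-bearing cells."""
    counts: dict[tuple[int, int], int] = {}
    n_with = 0
    for cell in cells:
        cat = (cell.count(channel_a), cell.count(channel_b))
        counts[cat] = counts.get(cat, 0) + 1
        if cat != (0, 0):
            n_with += 1
    percentages = {
        cat: 100.0 * n / n_with
        for cat, n in counts.items() if cat != (0, 0)
    } if n_with else {}
    n_cells = len(cells)
    no_focus = counts.get((0, 0), 0)
    return FociRepartition(
        counts=counts, percentages=percentages,
        no_focus_percent=100.0 * no_focus / n_cells if n_cells else 0.0,
        n_cells=n_cells, n_with_foci=n_with,
    )


@dataclass
class ThreeFociResult:
    frac_a_first: float   # fraction of (2, 1) cells: channel A already separated
    frac_b_first: float   # fraction of (1, 2) cells
    n_considered: int
    n_excluded: int       # 3-focus cells in patterns other than (1,2)/(2,1)


def classify_three_foci(cells: list[CellRecord], channel_a: str, channel_b: str) -> ThreeFociResult:
    """Separation order among cells with exactly 3 foci over two channels.

    A (2, 1) pattern means the channel-A locus has duplicated and
    separated while channel B has not — "A separated first" — and
    symmetrically for (1, 2).  Other 3-focus patterns (e.g. (3, 0)) are
    excluded and counted.
    """
    n_a_first = n_b_first = n_excluded = 0
    for cell in cells:
        a, b = cell.count(channel_a), cell.count(channel_b)
        if a + b != 3:
            continue
        if (a, b) == (2, 1):
            n_a_first += 1
        elif (a, b) == (1, 2):
            n_b_first += 1
        else:
            n_excluded += 1
    n = n_a_first + n_b_first
    return ThreeFociResult(
        frac_a_first=n_a_first / n if n else float("nan"),
        frac_b_first=n_b_first / n if n else float("nan"),
        n_considered=n, n_excluded=n_excluded,
    )


def anucleate_fraction(cells: list[CellRecord], n_boot: int = 1000,
                       seed: int | None = None, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Percentage of cells without a nucleoid, with a percentile bootstrap CI."""
    flags = np.array([not c.nucleoid_present for c in cells], dtype=float)
    if flags.size == 0:
        raise ValueError("no cells supplied")
    pct = 100.0 * flags.mean()
    rng = np.random.default_rng(seed)
    boots = 100.0 * rng.choice(flags, size=(n_boot, flags.size), replace=True).mean(axis=1)
    alpha = (1 - ci) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return float(pct), (float(lo), float(hi))


# --- tabular I/O -----------------------------------------------------------

CELLS_COLUMNS = ["cell_id", "cell_length", "nucleoid", "channel", "rel_pos"]


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Long-format table, one row per focus; focus-free cells get one row
    with an empty channel."""
    rows = []
    for c in cells:
        if c.foci:
            for ch, p in c.foci:
                rows.append((c.cell_id, c.length, int(c.nucleoid_present), ch, p))
        else:
            rows.append((c.cell_id, c.length, int(c.nucleoid_present), "", np.nan))
    return pd.DataFrame(rows, columns=CELLS_COLUMNS)


def frame_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    cells = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        first = group.iloc[0]
        foci = [(str(r.channel), float(r.rel_pos))
                for r in group.itertuples()
                if isinstance(r.channel, str) and r.channel and np.isfinite(r.rel_pos)]
        cells.append(CellRecord(str(cell_id), float(first.cell_length),
                                bool(first.nucleoid), foci))
    return cells


def read_cells_tsv(path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"cell_id": str, "channel": str}, keep_default_na=False,
                     na_values={"rel_pos": [""]})
    df["rel_pos"] = pd.to_numeric(df["rel_pos"], errors="coerce")
    return frame_to_cells(df)


def write_cells_tsv(cells: list[CellRecord], path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        cells_to_frame(cells).to_csv(fh, sep="\t", index=False)
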