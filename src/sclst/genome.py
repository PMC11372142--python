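"""Genome coordinate frame, fixed-width bin grids, and interval resources.

All internal coordinates are 0-based half-open. BED files are read/written
natively in that convention; SEG files (1-based inclusive) are converted at
the boundary by the pipeline I/O helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Per-bin mappability below this is masked out of every analysis. This plays
#: the role a read-level mapping-quality cutoff plays upstream of binning:
#: regions whose alignments cannot be trusted contribute no usable bins.
DEFAULT_MAPPABILITY_THRESHOLD = 0.5

#: Default bin width (bp) for low-pass WGS copy-number profiling.
DEFAULT_BIN_WIDTH = 500_000

# GRCh37/hg19 autosome lengths (bp).
HG19_AUTOSOME_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: a name, a length in bp, optionally a centromere."""

    name: str
    length: int
    centromere: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: non-positive length")
        if self.centromere is not None and not (0 < self.centromere < self.length):
            raise ValueError(
                f"chromosome {self.name!r}: centromere {self.centromere} "
                f"outside (0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes defining the coordinate frame."""

    chromosomes: tuple[ChromosomeSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        if not self.chromosomes:
            raise ValueError("empty genome")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)


def hg19_autosomes() -> GenomeModel:
    """The 22 GRCh37 autosomes at their reference lengths."""
    return GenomeModel(
        tuple(ChromosomeSpec(n, l) for n, l in HG19_AUTOSOME_LENGTHS.items())
    )


def toy_genome(n_chroms: int = 3, length: int = 100_000_000,
                names: Sequence[str] | None = None) -> GenomeModel:
    """A desk-scale genome (default three 100 Mb chromosomes) for simulation
    and testing; full hg19 ships as :func:`hg19_autosomes`."""
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chroms)]
    return GenomeModel(tuple(ChromosomeSpec(n, length) for n in names))


class BinGrid:
    """A fixed-width tiling of a genome, with per-bin GC, mappability and
    blacklist annotations and a derived usability mask.

    The grid is stored as a DataFrame with columns
    ``chrom, start, end, gc, mappability, blacklisted, usable``.
    Bins tile every chromosome contiguously left-to-right; the last bin of a
    chromosome may be shorter than ``width``.
    """

    COLUMNS = ["chrom", "start", "end", "gc", "mappability", "blacklisted", "usable"]

    def __init__(self, genome: GenomeModel, width: int, bins: pd.DataFrame,
                 mappability_threshold: float = DEFAULT_MAPPABILITY_THRESHOLD):
        self.genome = genome
        self.width = width
        self.mappability_threshold = mappability_threshold
        self.bins = bins.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        b = self.bins
        if list(b.columns) != self.COLUMNS:
            raise ValueError(f"grid columns must be {self.COLUMNS}")
        for chrom in self.genome.names:
            sub = b[b["chrom"] == chrom]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(sub) == 0:
                raise ValueError(f"chromosome {chrom} has no bins")
            if starts[0] != 0 or ends[-1] != self.genome[chrom].length:
                raise ValueError(f"bins do not tile {chrom}")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"bins not contiguous on {chrom}")
            if not np.all(ends - starts > 0) or np.any(ends - starts > self.width):
                raise ValueError(f"bad bin widths on {chrom}")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def usable(self) -> np.ndarray:
        return self.bins["usable"].to_numpy(dtype=bool)

    @property
    def chrom(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.bins["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.bins["end"].to_numpy()

    def recompute_usable(self) -> None:
        """usable = not blacklisted and mappability >= threshold."""
        b = self.bins
        b["usable"] = (~b["blacklisted"]) & (
            b["mappability"] >= self.mappability_threshold
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Row slice of the grid for each chromosome, in genome order."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        for name in self.genome.names:
            idx = np.flatnonzero(chroms == name)
            out[name] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_tsv(self, path_or_buf) -> None:
        self.bins.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf, genome: GenomeModel, width: int) -> "BinGrid":
        bins = pd.read_csv(path_or_buf, sep="\t")
        bins["blacklisted"] = bins["blacklisted"].astype(bool)
        bins["usable"] = bins["usable"].astype(bool)
        return cls(genome, width, bins)


def build_bin_grid(genome: GenomeModel, width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Tile every chromosome with ``width``-bp bins (0-based half-open).

    Each chromosome gets ``ceil(length / width)`` bins; the last bin is
    truncated at the chromosome end. GC defaults to 0.5, mappability to 1.0,
    nothing blacklisted — call :func:`annotate_gc_mappability` and
    :func:`apply_blacklist` to annotate.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for c in genome.chromosomes:
        starts = np.arange(0, c.length, width, dtype=np.int64)
        ends = np.minimum(starts + width, c.length)
        rows.append(pd.DataFrame({"chrom": c.name, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    bins["gc"] = 0.5
    bins["mappability"] = 1.0
    bins["blacklisted"] = False
    bins["usable"] = True
    return BinGrid(genome, width, bins)


def annotate_gc_mappability(grid: BinGrid, gc_track=None, map_track=None,
                            default_gc: float = 0.5,
                            default_mappability: float = 1.0) -> BinGrid:
    """Attach per-bin GC fraction and mappability, then refresh the mask.

    Tracks are arrays aligned to the grid (one value per bin) or ``None`` to
    use the constant default. Modifies and returns ``grid``.
    """
    n = len(grid)
    for name, track, default in (("gc", gc_track, default_gc),
                                 ("mappability", map_track, default_mappability)):
        if track is None:
            vals = np.full(n, default, dtype=float)
        else:
            vals = np.asarray(track, dtype=float)
            if len(vals) != n:
                raise ValueError(
                    f"{name} track has {len(vals)} values for {n} bins"
                )
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"{name} values must lie in [0, 1]")
        grid.bins[name] = vals
    grid.recompute_usable()
    return grid


def apply_blacklist(grid: BinGrid, intervals: pd.DataFrame,
                    min_overlap: float = 0.5) -> BinGrid:
    """Flag bins overlapped by blacklist intervals (ENCODE-style excluded
    regions). A bin is blacklisted when intervals cover more than
    ``min_overlap`` of it; refreshes the usability mask."""
    covered = np.zeros(len(grid), dtype=float)
    starts, ends, chroms = grid.start, grid.end, grid.chrom
    for _, iv in intervals.iterrows():
        on = chroms == iv["chrom"]
        ov = np.minimum(ends, iv["end"]) - np.maximum(starts, iv["start"])
        covered[on] += np.clip(ov[on], 0, None)
    frac = covered / (ends - starts)
    grid.bins["blacklisted"] = grid.bins["blacklisted"] | (frac > min_overlap)
    grid.recompute_usable()
    return grid


# ---------------------------------------------------------------------------
# Interval resources: BED loading, gene panel
# ---------------------------------------------------------------------------

GENE_CATEGORIES = ("HRD", "TNBC_driver")


@dataclass
class GenePanel:
    """The gene panel the classifier's covariates come from.

    A DataFrame with columns ``symbol, chrom, start, end, category``;
    categories distinguish homologous-recombination-deficiency (HRD) related
    genes from TNBC driver genes.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = ["symbol", "chrom", "start", "end", "category"]
        if list(t.columns) != required:
            t = t[required]
        if t["symbol"].duplicated().any():
            dupes = t.loc[t["symbol"].duplicated(), "symbol"].tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        bad = ~t["category"].isin(GENE_CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown categories: {sorted(t.loc[bad, 'category'].unique())}"
            )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    def to_bed(self, path) -> None:
        out = self.table[["chrom", "start", "end", "symbol", "category"]]
        out.to_csv(path, sep="\t", index=False, header=False)


def load_intervals(path, genome: GenomeModel) -> pd.DataFrame:
    """Read a BED file (>=3 tab-separated columns, 0-based half-open) and
    validate every record against the genome.

    Returns a DataFrame with ``chrom, start, end`` plus ``name`` / ``score``
    when 4th/5th columns are present. Malformed coordinates, unknown
    chromosomes and out-of-range intervals raise with the offending 1-based
    line numbers.
    """
    rows = []
    errors = []
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            errors.append(f"line {lineno}: fewer than 3 columns")
            continue
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            errors.append(f"line {lineno}: non-integer coordinates")
            continue
        if chrom not in genome:
            errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
            continue
        if not (0 <= start < end <= genome[chrom].length):
            errors.append(
                f"line {lineno}: interval [{start}, {end}) outside {chrom} "
                f"(length {genome[chrom].length})"
            )
            continue
        row = {"chrom": chrom, "start": start, "end": end}
        if len(parts) > 3:
            row["name"] = parts[3]
        if len(parts) > 4:
            row["score"] = parts[4]
        rows.append(row)
    if errors:
        raise ValueError("invalid BED records: " + "; ".join(errors))
    cols = ["chrom", "start", "end"]
    if rows and "name" in rows[0]:
        cols.append("name")
    if rows and "score" in rows[0]:
        cols.append("score")
    return pd.DataFrame(rows, columns=cols)


def load_gene_panel(path, genome: GenomeModel) -> GenePanel:
    """Load a gene panel from a 5-column BED (chrom, start, end, symbol,
    category)."""
    df = load_intervals(path, genome)
    if "name" not in df.columns or "score" not in df.columns:
        raise ValueError("gene panel BED needs symbol (col 4) and category (col 5)")
    return GenePanel(df.rename(columns={"name": "symbol", "score": "category"})[
        ["symbol", "chrom", "start", "end", "category"]
    ])


# Fixture panel: the HRD-related and TNBC driver genes named in the study
# description, at approximate hg19 coordinates. The full 39-gene panel is an
# input the user supplies; this 15-gene subset is the shipped default.
_FIXTURE_PANEL_ROWS = [
    # symbol, chrom, start, end, category
    ("EXO1", "chr1", 242_011_676, 242_126_789, "HRD"),
    ("MYC", "chr8", 128_748_315, 128_753_680, "TNBC_driver"),
    ("WRN", "chr8", 30_890_778, 31_031_844, "HRD"),
    ("CDKN2A", "chr9", 21_967_751, 21_995_300, "TNBC_driver"),
    ("ABL1", "chr9", 133_589_333, 133_763_062, "TNBC_driver"),
    ("NOTCH1", "chr9", 139_388_896, 139_440_238, "TNBC_driver"),
    ("GATA3", "chr10", 8_096_667, 8_117_164, "TNBC_driver"),
    ("MAPK8", "chr10", 49_514_698, 49_647_402, "TNBC_driver"),
    ("BRCA2", "chr13", 32_889_611, 32_973_805, "HRD"),
    ("RB1", "chr13", 48_877_911, 49_056_122, "TNBC_driver"),
    ("RAD51", "chr15", 40_987_327, 41_024_356, "HRD"),
    ("BLM", "chr15", 91_260_578, 91_358_686, "HRD"),
    ("TP53", "chr17", 7_571_720, 7_590_868, "TNBC_driver"),
    ("BRCA1", "chr17", 41_196_312, 41_277_500, "HRD"),
    ("BCR", "chr22", 23_522_552, 23_660_224, "TNBC_driver"),
]


def fixture_panel() -> GenePanel:
    """The shipped 15-gene panel (hg19 coordinates), user-replaceable."""
    return GenePanel(pd.DataFrame(
        _FIXTURE_PANEL_ROWS,
        columns=["symbol", "chrom", "start", "end", "category"],
    ))


def synthetic_panel(genome: GenomeModel, n_genes: int, rng: np.random.Generator,
                    gene_length: int = 100_000) -> GenePanel:
    """Place ``n_genes`` synthetic genes uniformly on a genome — used when
    simulating on desk-scale genomes where the hg19 fixture panel does not
    apply."""
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    rows = []
    for i in range(n_genes):
        ci = rng.choice(len(lengths), p=lengths / lengths.sum())
        c = genome.chromosomes[ci]
        start = int(rng.integers(0, max(1, c.length - gene_length)))
        cat = "HRD" if i < n_genes // 3 else "TNBC_driver"
        rows.append((f"GENE{i + 1:03d}", c.name, start, start + gene_length, cat))
    return GenePanel(pd.DataFrame(
        rows, columns=["symbol", "chrom", "start", "end", "category"]
    ))
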