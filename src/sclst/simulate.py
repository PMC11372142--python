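"""Synthetic single-cell copy-number data with known ground truth.

The generator produces what the analysis pipeline consumes: per-cell binned
read counts on a fixed grid, distorted the way whole-genome-amplified
low-pass libraries are (GC bias, lognormal over-dispersion, regional
dropout), together with the integer copy-number truth each cell was emitted
from. Truth profiles carry oracle-computed LST counts, aberrancy flags and
gene states so that every pipeline stage can be scored for parameter
recovery without patient data.

The forward model starts and ends at bin counts; no read-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeModel, GenePanel

LST_MIN_SEGMENT_BP = 10_000_000
ABERRANT_SINGLE_MB = 12.5
ABERRANT_CUMULATIVE_MB = 37.5

#: Copy-number deltas and their probabilities. Losses slightly outnumber
#: gains, mirroring the deletion predominance seen in TNBC copy-number data.
DEFAULT_DELTA_DISTRIBUTION = {-2: 0.1, -1: 0.5, 1: 0.3, 2: 0.1}


@dataclass(frozen=True)
class CNEvent:
    """A single copy-number event: an interval and an integer copy delta."""

    chrom: str
    start: int
    end: int
    delta: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must precede end")
        if self.delta == 0:
            raise ValueError("event delta must be non-zero")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``n_clonal_events`` and ``n_private_events`` are Poisson means; clonal
    events are drawn once and shared by every cell, private events are drawn
    per cell. Event lengths are log-uniform over ``event_length_range``.
    ``depth`` is total reads per cell (default comfortably above the
    400,000-read QC floor); ``wga_dispersion`` is the sigma of the per-bin
    lognormal amplification factor; ``dropout_rate`` is the genome fraction
    in contiguous low-yield regions (expected count scaled by 0.05).
    """

    #: Defaults emulate a CTC-like cohort on the full autosome frame:
    #: ~26 events per cell gives mean CNA counts near 30 and per-cell LST
    #: counts spanning roughly 0-18 with a low median, the regime reported
    #: for patient-derived single cells.
    n_cells: int = 50
    n_clonal_events: float = 6.0
    n_private_events: float = 20.0
    event_length_range: tuple[int, int] = (1_000_000, 15_000_000)
    delta_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTA_DISTRIBUTION))
    depth: int = 1_000_000
    wga_dispersion: float = 0.3
    dropout_rate: float = 0.01
    gc_bias_strength: float = 0.3
    ploidy: int = 2
    #: truth LST is evaluated with boundaries rounded to this resolution
    #: (the analysis bin width); None keeps exact bp boundaries
    truth_snap_bp: int | None = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.wga_dispersion < 0:
            raise ValueError("wga_dispersion must be non-negative")
        lo, hi = self.event_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid event_length_range")


@dataclass
class TruthProfile:
    """Ground truth for one simulated cell.

    ``segments`` is a DataFrame (chrom, start, end, cn) partitioning the
    genome into maximal runs of constant integer copy number. ``true_lst``,
    ``true_aberrant`` and ``true_gene_states`` are computed from the
    segments by the oracle functions below at construction time.
    """

    cell_id: str
    ploidy: int
    events: list[CNEvent]
    segments: pd.DataFrame
    true_lst: int
    true_aberrant: bool
    true_gene_states: pd.Series  # index: gene symbol; values in {-1, 0, +1}


@dataclass
class ClonePopulation:
    """Replicate cells sharing one clone's events, differing only in private
    events and noise — the design of cell-line reproducibility experiments."""

    clonal_events: list[CNEvent]
    replicates: list[TruthProfile]


# ---------------------------------------------------------------------------
# Truth construction and oracles
# ---------------------------------------------------------------------------

def truth_segments(genome: GenomeModel, events: list[CNEvent],
                   ploidy: int = 2) -> pd.DataFrame:
    """Integer copy number along the genome implied by additively composed
    events (floored at zero copies), as maximal constant-CN segments."""
    rows = []
    for c in genome.chromosomes:
        evs = [e for e in events if e.chrom == c.name]
        cuts = sorted({0, c.length, *(e.start for e in evs), *(e.end for e in evs)})
        prev_cn = None
        seg_start = 0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            cn = ploidy + sum(e.delta for e in evs if e.start <= lo and hi <= e.end)
            cn = max(cn, 0)
            if prev_cn is None:
                prev_cn, seg_start = cn, lo
            elif cn != prev_cn:
                rows.append((c.name, seg_start, lo, prev_cn))
                prev_cn, seg_start = cn, lo
        rows.append((c.name, seg_start, c.length, prev_cn))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])


def truth_state_segments(segments: pd.DataFrame, ploidy: int = 2):
    """Collapse integer-CN truth segments to loss/neutral/gain state runs —
    the quantity the 3-state calling pipeline actually observes."""
    from .lst import StateSegment
    from .pipeline import STATE_GAIN, STATE_LOSS, STATE_NEUTRAL

    names = {-1: STATE_LOSS, 0: STATE_NEUTRAL, 1: STATE_GAIN}
    out = []
    for _, sub in segments.groupby("chrom", sort=False):
        runs = []
        for _, s in sub.iterrows():
            state = int(np.sign(s["cn"] - ploidy))
            if runs and runs[-1][2] == state:
                runs[-1][1] = s["end"]
            else:
                runs.append([s["start"], s["end"], state])
        out.extend(StateSegment(sub["chrom"].iloc[0], r[0], r[1], names[r[2]])
                   for r in runs)
    return out


def _snap_segments(state_segs, snap: int):
    """Round state-segment boundaries to the bin width, dropping runs that
    collapse; the analysis can never observe sub-bin boundary positions, so
    ground truth is evaluated at the same resolution."""
    from .lst import StateSegment

    out = []
    by_chrom: dict[str, list] = {}
    for s in state_segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        end_chrom = segs[-1].end
        bounds = [0] + [int(round(s.end / snap)) * snap for s in segs[:-1]] \
            + [end_chrom]
        prev = None
        for s, lo, hi in zip(segs, bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            if prev is not None and prev.state == s.state:
                out[-1] = StateSegment(chrom, prev.start, hi, s.state)
                prev = out[-1]
            else:
                out.append(StateSegment(chrom, lo, hi, s.state))
                prev = out[-1]
    return out


def lst_from_truth(segments: pd.DataFrame, ploidy: int = 2,
                   snap_bp: int | None = None) -> int:
    """Ground-truth LST count: the state-based LST metric (sub-3 Mb
    smoothing, two-flank >= 10 Mb rule) applied to the noiseless
    state-collapsed truth segments, so truth and pipeline estimate measure
    the same quantity. ``snap_bp`` rounds boundaries to the analysis bin
    width first."""
    from .lst import count_lst, smooth_segments

    state_segs = truth_state_segments(segments, ploidy)
    if snap_bp:
        state_segs = _snap_segments(state_segs, snap_bp)
    return count_lst(smooth_segments(state_segs))


def aberrant_from_truth(segments: pd.DataFrame, ploidy: int = 2) -> bool:
    """Aberrancy on truth: any non-baseline region longer than 12.5 Mb, or
    non-baseline regions cumulatively exceeding 37.5 Mb."""
    dev = segments[segments["cn"] != ploidy]
    if dev.empty:
        return False
    mb = (dev["end"] - dev["start"]) / 1e6
    return bool((mb > ABERRANT_SINGLE_MB).any() or mb.sum() > ABERRANT_CUMULATIVE_MB)


def gene_states_from_truth(segments: pd.DataFrame, panel: GenePanel,
                           ploidy: int = 2) -> pd.Series:
    """Per-gene truth state in {-1, 0, +1}: sign of (majority-overlap copy
    number minus ploidy). Genes on chromosomes absent from the genome get 0."""
    states = {}
    for _, g in panel.table.iterrows():
        sub = segments[segments["chrom"] == g["chrom"]]
        if sub.empty:
            states[g["symbol"]] = 0
            continue
        ov = (np.minimum(sub["end"], g["end"])
              - np.maximum(sub["start"], g["start"])).clip(lower=0)
        if ov.sum() == 0:
            states[g["symbol"]] = 0
            continue
        cn = int(sub["cn"].iloc[int(np.argmax(ov.to_numpy()))])
        states[g["symbol"]] = int(np.sign(cn - ploidy))
    return pd.Series(states, dtype=int)


def _draw_events(rng: np.random.Generator, genome: GenomeModel,
                 config: SimConfig, n: int) -> list[CNEvent]:
    lo, hi = config.event_length_range
    max_len = max(c.length for c in genome.chromosomes)
    if lo > max_len:
        raise ValueError("event_length_range exceeds the longest chromosome")
    deltas = np.array(sorted(config.delta_distribution))
    probs = np.array([config.delta_distribution[d] for d in deltas], dtype=float)
    probs = probs / probs.sum()
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    events = []
    for _ in range(n):
        length = int(np.exp(rng.uniform(np.log(lo), np.log(min(hi, max_len)))))
        ok = lengths >= length
        p = np.where(ok, lengths, 0.0)
        ci = int(rng.choice(len(lengths), p=p / p.sum()))
        c = genome.chromosomes[ci]
        start = int(rng.integers(0, c.length - length + 1))
        delta = int(rng.choice(deltas, p=probs))
        events.append(CNEvent(c.name, start, start + length, delta))
    return events


def profile_from_events(cell_id: str, events: list[CNEvent],
                        genome: GenomeModel,
                        panel: GenePanel | None = None, ploidy: int = 2,
                        snap_bp: int | None = 500_000) -> TruthProfile:
    """Build a fully annotated truth profile from an explicit event list —
    the deterministic counterpart of :func:`simulate_truth`."""
    segs = truth_segments(genome, events, ploidy)
    return TruthProfile(
        cell_id=cell_id,
        ploidy=ploidy,
        events=events,
        segments=segs,
        true_lst=lst_from_truth(segs, ploidy, snap_bp),
        true_aberrant=aberrant_from_truth(segs, ploidy),
        true_gene_states=(gene_states_from_truth(segs, panel, ploidy)
                          if panel is not None else pd.Series(dtype=int)),
    )


def simulate_truth(config: SimConfig, genome: GenomeModel,
                   panel: GenePanel | None = None,
                   rng: np.random.Generator | None = None) -> list[TruthProfile]:
    """Draw a cohort of truth profiles: one shared clonal event set (count
    Poisson with mean ``n_clonal_events``) plus per-cell private events
    (Poisson mean ``n_private_events``)."""
    _, profiles = _simulate_with_clonal(config, genome, panel, rng)
    return profiles


def _simulate_with_clonal(config, genome, panel, rng):
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clonal = _draw_events(rng, genome, config,
                          int(rng.poisson(config.n_clonal_events)))
    profiles = []
    for i in range(config.n_cells):
        private = _draw_events(rng, genome, config,
                               int(rng.poisson(config.n_private_events)))
        profiles.append(profile_from_events(
            f"cell{i + 1:03d}", clonal + private, genome, panel,
            config.ploidy, config.truth_snap_bp))
    return clonal, profiles


def simulate_clone_replicates(config: SimConfig, genome: GenomeModel,
                              panel: GenePanel | None, n_replicates: int,
                              rng: np.random.Generator | None = None
                              ) -> ClonePopulation:
    """Replicate design: one clone, ``n_replicates`` cells sharing its events."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = replace(config, n_cells=n_replicates)
    clonal, profiles = _simulate_with_clonal(cfg, genome, panel, rng)
    return ClonePopulation(clonal_events=clonal, replicates=profiles)


# ---------------------------------------------------------------------------
# Forward model: truth -> binned read counts
# ---------------------------------------------------------------------------

def gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Quadratic multiplicative amplification bias centered at GC = 0.45,
    floored at 0.1 — the smooth bias the GC-correction stage must remove."""
    return np.maximum(0.1, 1.0 - strength * ((gc - 0.45) / 0.25) ** 2)


def bin_copy_number(truth: TruthProfile, grid: BinGrid) -> np.ndarray:
    """Overlap-weighted mean integer copy number per grid bin."""
    cn = np.zeros(len(grid), dtype=float)
    starts, ends, chroms = grid.start, grid.end, grid.chrom
    widths = (ends - starts).astype(float)
    for _, seg in truth.segments.iterrows():
        on = chroms == seg["chrom"]
        ov = np.minimum(ends, seg["end"]) - np.maximum(starts, seg["start"])
        cn[on] += np.clip(ov[on], 0, None) / widths[on] * seg["cn"]
    return cn


def _dropout_mask(rng: np.random.Generator, grid: BinGrid,
                  dropout_rate: float) -> np.ndarray:
    """Contiguous low-yield regions totalling ``dropout_rate`` of the bins.
    Regional (not i.i.d.) because WGA failure is regional."""
    n = len(grid)
    mask = np.zeros(n, dtype=bool)
    budget = int(round(dropout_rate * n))
    while budget > 0:
        size = int(min(budget, max(1, rng.integers(2, 11))))
        start = int(rng.integers(0, n - size + 1))
        mask[start:start + size] = True
        budget -= size
    return mask


def emit_bin_counts(truth: TruthProfile, grid: BinGrid, config: SimConfig,
                    rng: np.random.Generator | None = None):
    """Emit observed integer read counts for one cell.

    Expected count per usable bin is proportional to copy number times the
    GC-bias curve times mappability, normalised to sum to ``depth``; dropout
    regions have their expectation scaled by 0.05. Counts are drawn
    multinomially (exactly ``depth`` reads), then multiplied per-bin by a
    lognormal WGA factor (sigma = ``wga_dispersion``) and re-rounded.
    """
    from .pipeline import BinCounts  # local import; pipeline never imports us

    if rng is None:
        rng = np.random.default_rng(config.seed)
    usable = grid.usable
    if not usable.any():
        raise ValueError("grid has no usable bins")
    cn = bin_copy_number(truth, grid)
    weight = cn * gc_bias_curve(grid.bins["gc"].to_numpy(), config.gc_bias_strength)
    weight = weight * grid.bins["mappability"].to_numpy()
    weight[~usable] = 0.0
    if config.dropout_rate > 0:
        weight[_dropout_mask(rng, grid, config.dropout_rate)] *= 0.05
    if weight.sum() <= 0:
        raise ValueError("degenerate profile: zero total expected count")
    p = weight / weight.sum()
    counts = rng.multinomial(config.depth, p).astype(float)
    if config.wga_dispersion > 0:
        counts *= rng.lognormal(0.0, config.wga_dispersion, size=len(counts))
    counts = np.rint(counts).astype(np.int64)
    return BinCounts(cell_id=truth.cell_id, counts=counts)


def simulate_cohort(config: SimConfig, genome: GenomeModel, grid: BinGrid,
                    panel: GenePanel | None = None):
    """Truth plus emitted counts for a whole cohort from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    profiles = simulate_truth(config, genome, panel, rng)
    counts = [emit_bin_counts(t, grid, config, rng) for t in profiles]
    return profiles, counts


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def counts_to_tsv(counts_list, grid: BinGrid, path) -> None:
    """Long-format bin counts: cell_id, chrom, start, end, count."""
    frames = []
    for bc in counts_list:
        frames.append(pd.DataFrame({
            "cell_id": bc.cell_id, "chrom": grid.chrom,
            "start": grid.start, "end": grid.end, "count": bc.counts,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def counts_from_tsv(path, grid: BinGrid):
    """Read long-format counts back, validating bin alignment per cell."""
    from .pipeline import BinCounts

    df = pd.read_csv(path, sep="\t")
    out = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        if len(sub) != len(grid):
            raise ValueError(f"{cell_id}: {len(sub)} rows for {len(grid)} bins")
        if (not (sub["chrom"].to_numpy() == grid.chrom).all()
                or not (sub["start"].to_numpy() == grid.start).all()):
            raise ValueError(f"{cell_id}: bins do not match the grid")
        out.append(BinCounts(cell_id=str(cell_id),
                             counts=sub["count"].to_numpy(np.int64)))
    return out


def truth_to_seg(profiles: list[TruthProfile], path) -> None:
    """Truth segments as a SEG table (1-based inclusive, integer CN column)."""
    rows = []
    for p in profiles:
        for _, s in p.segments.iterrows():
            rows.append((p.cell_id, s["chrom"], s["start"] + 1, s["end"], s["cn"]))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "cn"]).to_csv(
        path, sep="\t", index=False)


def truth_summary(profiles: list[TruthProfile]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [p.cell_id for p in profiles],
        "true_lst": [p.true_lst for p in profiles],
        "true_aberrant": [p.true_aberrant for p in profiles],
    })
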