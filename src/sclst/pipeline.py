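"""Per-cell copy-number calling from binned low-pass WGS read counts.

Stages, in run order: read-count QC, GC-corrected log2-ratio normalization,
recursive binary (CBS-style) segmentation with a seeded permutation test,
gain/neutral/loss calling with residual and chromosome-19 filtering, and
the large-aberration classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid

# QC: cells below this read total are excluded from all downstream analysis.
MIN_TOTAL_READS = 400_000
# QC: cells with a genomic integrity index (wet-lab WGA quality score, 0-4)
# below this are excluded when the score is supplied.
MIN_GII = 2

# Calling thresholds on segment mean log2 ratio. They sit between noise and
# the single-copy closed forms (+0.585 for 3/2, -1.0 for 1/2).
GAIN_LOG2 = 0.3
LOSS_LOG2 = -0.3

# Bins deviating from their local level by more than this many robust SDs
# are residual outliers; segments dominated by outliers are not called.
RESIDUAL_SD_FACTOR = 4.0

ABERRANT_SINGLE_MB = 12.5
ABERRANT_CUMULATIVE_MB = 37.5

#: Chromosomes never called gain/loss: chr19's GC-driven coverage depression
#: in amplified single-cell libraries produces spurious deletion calls.
CNA_EXCLUDED_CHROMS = ("chr19",)


@dataclass
class BinCounts:
    """Raw read counts for one cell on a fixed bin grid."""

    cell_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"{self.cell_id}: negative counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class QCResult:
    cell_id: str
    total_reads: int
    gii: int | None
    passed: bool
    reason: str


def qc_filter(cells: list[BinCounts],
              gii_table: dict[str, int] | None = None,
              min_reads: int = MIN_TOTAL_READS,
              min_gii: int = MIN_GII) -> list[QCResult]:
    """Apply the per-cell QC gates: total reads >= 400,000 and, when a
    genomic integrity index is supplied, GII >= 2. Pure predicate."""
    results = []
    for bc in cells:
        gii = None if gii_table is None else gii_table.get(bc.cell_id)
        reasons = []
        if bc.total_reads < min_reads:
            reasons.append(
                f"total reads {bc.total_reads} < {min_reads}")
        if gii is not None and gii < min_gii:
            reasons.append(f"GII {gii} < {min_gii}")
        results.append(QCResult(
            cell_id=bc.cell_id, total_reads=bc.total_reads, gii=gii,
            passed=not reasons, reason="; ".join(reasons) or "ok"))
    return results


def qc_report(results: list[QCResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": r.cell_id, "total_reads": r.total_reads,
        "gii": "" if r.gii is None else r.gii,
        "passed": r.passed, "reason": r.reason,
    } for r in results])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class CopyRatioProfile:
    """GC-corrected, median-centered log2 copy ratios for one cell.

    ``log2ratio`` has one entry per grid bin (NaN where unusable);
    ``residual_sd`` is the robust per-bin noise scale estimated from
    consecutive-bin first differences; ``residual_outlier`` flags bins more
    than 4 robust SDs from their local level.
    """

    cell_id: str
    log2ratio: np.ndarray
    usable: np.ndarray
    residual_sd: float
    residual_outlier: np.ndarray


def _log_mode(values: np.ndarray) -> float:
    """Modal value of a sample: the point of highest Gaussian-kernel density
    (Silverman bandwidth on a robust MAD scale), evaluated at the sample
    points themselves — shift-equivariant, hence compatible with exact
    normalization idempotence."""
    if len(values) == 1:
        return float(values[0])
    scale = 1.4826 * np.median(np.abs(values - np.median(values)))
    bandwidth = max(1.06 * scale * len(values) ** -0.2, 0.05)
    d = values[:, None] - values[None, :]
    dens = np.exp(-0.5 * (d / bandwidth) ** 2).sum(axis=1)
    return float(values[int(np.argmax(dens))])


def _gc_correct_log(l: np.ndarray, gc: np.ndarray, n_deciles: int = 10
                    ) -> np.ndarray:
    """Per-GC-decile rescaling in log space: each decile's *modal* log count
    is aligned across deciles.

    The mode (densest level) rather than the median anchors each decile on
    its dominant copy state, so a decile partially covered by a genuine
    large gain or loss is not mis-rescaled the way a contaminated median
    would be.
    """
    out = l.copy()
    if len(np.unique(gc)) < 2:
        return out
    edges = np.unique(np.quantile(gc, np.linspace(0, 1, n_deciles + 1)))
    which = np.clip(np.searchsorted(edges, gc, side="right") - 1,
                    0, len(edges) - 2)
    for d in range(len(edges) - 1):
        sel = which == d
        if sel.any():
            out[sel] -= _log_mode(out[sel])
    return out


def _center_log2(values: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """log2 of counts (floored at 0.5 reads), GC-corrected, minus the median
    log2 — so the usable-bin median log2 ratio is exactly zero."""
    l = np.log2(np.maximum(values, 0.5))
    l = _gc_correct_log(l, gc)
    return l - np.median(l)


def _robust_diff_sd(l: np.ndarray, chrom_of: np.ndarray) -> float:
    """Noise SD from within-chromosome consecutive-bin first differences,
    via the MAD: insensitive to true copy-number steps, which are sparse."""
    diffs = []
    for c in pd.unique(chrom_of):
        v = l[chrom_of == c]
        if len(v) > 1:
            diffs.append(np.diff(v))
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def _rolling_median(l: np.ndarray, chrom_of: np.ndarray,
                    window: int = 15) -> np.ndarray:
    out = np.empty_like(l)
    for c in pd.unique(chrom_of):
        sel = chrom_of == c
        out[sel] = (pd.Series(l[sel])
                    .rolling(window, center=True, min_periods=1)
                    .median().to_numpy())
    return out


def normalize(counts: BinCounts, grid: BinGrid,
              min_usable_bins: int = 100) -> CopyRatioProfile:
    """Turn raw counts into a centered log2 copy-ratio profile.

    Unusable bins are masked; GC bias is removed by per-GC-decile rescaling
    anchored on each decile's modal log count (robust to deciles partially
    covered by true CNAs); ratios are log2 values centered on their median
    (so the
    usable-bin median is exactly 0); the residual noise scale comes from a
    robust estimate over consecutive-bin differences, and bins further than
    4 of those SDs from a 15-bin rolling median are flagged as outliers.
    """
    if len(counts.counts) != len(grid):
        raise ValueError("counts length does not match grid")
    usable = grid.usable.copy()
    if usable.sum() < min_usable_bins:
        raise ValueError(
            f"{counts.cell_id}: only {int(usable.sum())} usable bins "
            f"(< {min_usable_bins}); profile unreliable")
    vals = counts.counts[usable].astype(float)
    gc = grid.bins["gc"].to_numpy()[usable]
    chrom_of = grid.chrom[usable]

    l = _center_log2(vals, gc)
    sd = _robust_diff_sd(l, chrom_of)
    local = _rolling_median(l, chrom_of)
    outlier_u = np.abs(l - local) > RESIDUAL_SD_FACTOR * sd if sd > 0 else \
        np.zeros(len(l), dtype=bool)

    log2ratio = np.full(len(grid), np.nan)
    log2ratio[usable] = l
    outlier = np.zeros(len(grid), dtype=bool)
    outlier[usable] = outlier_u
    return CopyRatioProfile(cell_id=counts.cell_id, log2ratio=log2ratio,
                            usable=usable, residual_sd=sd,
                            residual_outlier=outlier)


# ---------------------------------------------------------------------------
# Segmentation (CBS-style recursive binary splitting, permutation-tested)
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A constant-level run of usable bins on one chromosome."""

    cell_id: str
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    bin_indices: np.ndarray = field(repr=False, default=None)


class _ArcFamily:
    """The admissible arcs [i, j) of an n-bin segment, with length-dependent
    constants precomputed: the arc, its complement, and every resulting
    non-empty piece must hold >= min_size bins."""

    _cache: dict[tuple[int, int], "_ArcFamily"] = {}

    def __init__(self, n: int, min_size: int):
        idx = np.arange(n + 1)
        L = idx[None, :] - idx[:, None]
        valid = (L >= min_size) & ((n - L) >= min_size)
        valid &= (idx[:, None] == 0) | (idx[:, None] >= min_size)
        valid &= (idx[None, :] == n) | ((n - idx[None, :]) >= min_size)
        self.n = n
        self.i, self.j = (a.astype(np.intp) for a in np.nonzero(valid))
        La = (self.j - self.i).astype(float)
        self.inv_l = 1.0 / La
        self.inv_r = 1.0 / (n - La)
        self.denom = np.sqrt(self.inv_l + self.inv_r) / np.sqrt(max(n - 2, 1))

    @classmethod
    def get(cls, n: int, min_size: int) -> "_ArcFamily":
        key = (n, min_size)
        if key not in cls._cache:
            if len(cls._cache) > 256:
                cls._cache.clear()
            cls._cache[key] = cls(n, min_size)
        return cls._cache[key]

    def t_stats_sq(self, X: np.ndarray) -> np.ndarray:
        """Squared t statistic for every admissible arc; X is (..., n).
        Monotone in |t|, so maxima and comparisons carry over."""
        dt = X.dtype
        zeros = np.zeros(X.shape[:-1] + (1,), dtype=dt)
        cs = np.concatenate([zeros, np.cumsum(X, axis=-1)], axis=-1)
        cs2 = np.concatenate([zeros, np.cumsum(X * X, axis=-1)], axis=-1)
        A = cs[..., self.j] - cs[..., self.i]
        A2 = cs2[..., self.j] - cs2[..., self.i]
        T = cs[..., -1][..., None]
        T2 = cs2[..., -1][..., None]
        B = T - A
        diff = A * self.inv_l.astype(dt) - B * self.inv_r.astype(dt)
        rss = (A2 - A * A * self.inv_l.astype(dt)) \
            + (T2 - A2 - B * B * self.inv_r.astype(dt))
        denom2 = (self.denom * self.denom).astype(dt)
        return diff * diff / (np.maximum(rss, 0.0) * denom2 + dt.type(1e-24))

    def max_t_sq_rows(self, X: np.ndarray, min_size: int) -> np.ndarray:
        """Row-wise max squared t over admissible arcs, iterating over arc
        lengths with contiguous slices — the fast path for permutation
        batches."""
        dt = X.dtype
        c, n = X.shape
        zeros = np.zeros((c, 1), dtype=dt)
        cs = np.concatenate([zeros, np.cumsum(X, axis=1)], axis=1)
        cs2 = np.concatenate([zeros, np.cumsum(X * X, axis=1)], axis=1)
        T = cs[:, -1:]
        T2 = cs2[:, -1:]
        scale = dt.type(max(n - 2, 1))
        best = np.zeros(c, dtype=dt)
        for L in range(min_size, n - min_size + 1):
            A = cs[:, L:] - cs[:, :-L]
            A2 = cs2[:, L:] - cs2[:, :-L]
            B = T - A
            inv_l = dt.type(1.0 / L)
            inv_r = dt.type(1.0 / (n - L))
            denom2 = (inv_l + inv_r) / scale
            diff = A * inv_l - B * inv_r
            rss = (A2 - A * A * inv_l) + (T2 - A2 - B * B * inv_r)
            tsq = diff * diff / (np.maximum(rss, 0) * denom2
                                 + dt.type(1e-24))
            # start positions i in [1, min_size) and ends j in
            # (n - min_size, n) would leave a piece below min_size
            if min_size > 1:
                tsq[:, 1:min_size] = 0
                lo = n - L - min_size + 1
                tsq[:, max(lo, 0):n - L] = 0
            m = tsq.max(axis=1)
            np.maximum(best, m, out=best)
        return best


def _arc_scan(x: np.ndarray, min_size: int) -> tuple[float, int, int]:
    """Best arc of one profile: (max |t|, i, j)."""
    fam = _ArcFamily.get(len(x), min_size)
    if len(fam.i) == 0:
        return 0.0, 0, 0
    t2 = fam.t_stats_sq(x)
    k = int(np.argmax(t2))
    return float(np.sqrt(t2[k])), int(fam.i[k]), int(fam.j[k])


def _perm_pvalue(x: np.ndarray, obs: float, params: "SegmentationParams",
                 rng: np.random.Generator) -> float:
    """Permutation p-value for the max arc statistic, evaluated in chunks
    with early stopping: once enough permutations reach ``obs`` that the
    final p-value cannot fall below alpha, the remainder cannot change the
    accept/reject decision."""
    n = len(x)
    if obs > 1e8:  # essentially zero within-piece variance: no permuted
        return 1.0 / (params.n_permutations + 1)  # arrangement competes
    B = params.n_permutations
    fam = _ArcFamily.get(n, params.min_segment_bins)
    reject_count = params.alpha * (B + 1)  # p >= alpha once 1+exceed >= this
    # sequential testing (Besag-Clifford): stop as soon as the decision
    # against alpha is settled (enough exceedances) or practically certain
    # (none at all after early_stop permutations)
    early_stop = max(int(2.0 / params.alpha), 1)
    chunk = int(np.clip(8_000_000 // max(len(fam.i), 1), 16, 256))
    obs_sq = np.float32(obs) * np.float32(obs)
    x32 = x.astype(np.float32)
    exceed, done, null_max = 0, 0, 0.0
    while done < B:
        c = min(chunk, B - done)
        P = rng.permuted(np.broadcast_to(x32, (c, n)).copy(), axis=1)
        null = fam.max_t_sq_rows(P, params.min_segment_bins)
        null_max = max(null_max, float(null.max()))
        exceed += int((null >= obs_sq).sum())
        done += c
        if 1 + exceed >= reject_count:
            return max((1 + exceed) / (done + 1), params.alpha)
        if exceed == 0:
            # clear-cut split: the observed statistic is far beyond every
            # permutation seen; further sampling cannot plausibly change
            # the decision against alpha
            if done >= 48 and obs_sq >= 2.25 * null_max:
                return 1.0 / (B + 1)
            if done >= early_stop:
                return 1.0 / (done + 1)
    return (1 + exceed) / (done + 1)


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_segment_bins: int = 2
    merge_delta: float = 0.1
    winsor_sd: float = 3.0  # outlier clip (robust SDs) for break detection


def _segment_recursive(x: np.ndarray, offset: int, params: SegmentationParams,
                       rng: np.random.Generator, breaks: list[int]) -> None:
    """CBS recursion: find the best arc, permutation-test it, and when
    accepted place its (up to two) breakpoints and recurse into the pieces."""
    n = len(x)
    if n < 2 * params.min_segment_bins:
        return
    obs, i, j = _arc_scan(x, params.min_segment_bins)
    if obs == 0:
        return
    p = _perm_pvalue(x, obs, params, rng)
    if p >= params.alpha:
        return
    points = [k for k in (i, j) if 0 < k < n]
    breaks.extend(offset + k for k in points)
    edges = [0] + points + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        _segment_recursive(x[a:b], offset + a, params, rng, breaks)


def _refine_breaks(x: np.ndarray, breaks: list[int], min_size: int,
                   window: int = 3, n_rounds: int = 2) -> list[int]:
    """Locally re-fit each breakpoint: within +/- ``window`` bins, place the
    boundary where the residual sum of squares of the two flanking segments
    is smallest. Corrects the edge-bin absorption bias of the arc scan."""
    bks = sorted(breaks)
    for _ in range(n_rounds):
        moved = False
        for bi, b in enumerate(bks):
            lo = bks[bi - 1] if bi > 0 else 0
            hi = bks[bi + 1] if bi + 1 < len(bks) else len(x)
            cand = [k for k in range(max(lo + min_size, b - window),
                                     min(hi - min_size, b + window) + 1)]
            if not cand:
                continue
            def rss(k: int) -> float:
                a, c = x[lo:k], x[k:hi]
                return float(((a - a.mean()) ** 2).sum()
                             + ((c - c.mean()) ** 2).sum())
            best = min(cand, key=rss)
            if best != b:
                bks[bi] = best
                moved = True
        if not moved:
            break
    return sorted(set(bks))


def _merge_breaks(x: np.ndarray, breaks: list[int], delta: float) -> list[int]:
    """Drop the weakest break (smallest adjacent-mean gap) until every
    remaining adjacent pair of segments differs by at least ``delta``."""
    bks = sorted(breaks)
    while bks:
        edges = [0] + bks + [len(x)]
        means = [x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        worst = int(np.argmin(gaps))
        if gaps[worst] >= delta:
            break
        bks.pop(worst)
    return bks


def segment(profile: CopyRatioProfile, grid: BinGrid,
            params: SegmentationParams | None = None,
            seed: int = 0) -> list[Segment]:
    """Segment a profile chromosome by chromosome.

    Recursive binary splitting at the maximal two-sample |t| split, accepted
    when a seeded within-segment permutation test gives p < alpha; accepted
    splits recurse into both halves. Afterwards, adjacent segments whose
    means differ by less than ``merge_delta`` are merged back. A flat
    chromosome yields a single segment.
    """
    if params is None:
        params = SegmentationParams()
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    starts, ends = grid.start, grid.end
    for chrom, sl in grid.chrom_slices().items():
        idx = np.arange(sl.start, sl.stop)[profile.usable[sl]]
        if len(idx) == 0:
            continue
        x = profile.log2ratio[idx]
        # Winsorize for break detection only: isolated spikes (dropout,
        # zero-count bins) otherwise dominate the max-|t| permutation null
        # and mask genuine single-copy steps. Segment means use raw values.
        if profile.residual_sd > 0:
            local = _rolling_median(x, np.repeat(chrom, len(x)))
            lim = params.winsor_sd * profile.residual_sd
            xw = np.clip(x, local - lim, local + lim)
        else:
            xw = x
        breaks: list[int] = []
        _segment_recursive(xw, 0, params, rng, breaks)
        breaks = _refine_breaks(xw, breaks, params.min_segment_bins)
        bks = _merge_breaks(x, breaks, params.merge_delta)
        edges = [0] + bks + [len(x)]
        for a, b in zip(edges[:-1], edges[1:]):
            members = idx[a:b]
            segments.append(Segment(
                cell_id=profile.cell_id, chrom=chrom,
                start=int(starts[members[0]]), end=int(ends[members[-1]]),
                n_bins=len(members), mean_log2=float(x[a:b].mean()),
                bin_indices=members))
    return segments


# ---------------------------------------------------------------------------
# Calling, aberrancy, counting
# ---------------------------------------------------------------------------

STATE_GAIN = "gain"
STATE_NEUTRAL = "neutral"
STATE_LOSS = "loss"


@dataclass
class CNACall:
    """A segment with its gain/neutral/loss call."""

    cell_id: str
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    state: str

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class CNAProfile:
    cell_id: str
    calls: list[CNACall]
    n_gain: int
    n_loss: int
    aberrant: bool

    @property
    def n_cna(self) -> int:
        return self.n_gain + self.n_loss


def _modal_baseline(segments: list[Segment], bandwidth: float = 0.05,
                    span: float = 1.0) -> float:
    """Length-weighted modal segment mean: the log2 level of the most common
    copy state, taken as the cell's neutral baseline.

    Median centering leaves aberrant cells biased (a loss-heavy genome
    pushes its neutral segments above zero), so calling is anchored on the
    mode instead, evaluated by a weighted Gaussian kernel over segment
    means within +/- span of zero.
    """
    means = np.array([s.mean_log2 for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)
    near = np.abs(means) <= span
    if not near.any():
        return 0.0
    grid_pts = np.arange(-span, span + 1e-9, 0.01)
    dens = (weights[near, None]
            * np.exp(-0.5 * ((grid_pts[None, :] - means[near, None])
                             / bandwidth) ** 2)).sum(axis=0)
    return float(grid_pts[int(np.argmax(dens))])


def call_states(segments: list[Segment], profile: CopyRatioProfile,
                gain_threshold: float = GAIN_LOG2,
                loss_threshold: float = LOSS_LOG2,
                excluded_chroms: tuple[str, ...] = CNA_EXCLUDED_CHROMS,
                max_outlier_fraction: float = 0.5,
                recenter: bool = True,
                min_z: float = 3.0) -> list[CNACall]:
    """Call each segment gain/neutral/loss from its mean log2 ratio.

    With ``recenter`` (default) the thresholds are applied relative to the
    cell's modal copy-state level (see :func:`_modal_baseline`). A
    non-neutral call additionally requires the baseline deviation to exceed
    ``min_z`` standard errors (segment mean SE from the per-bin robust
    noise scale) — segment selection biases marginal means outward, and the
    gate keeps such selection noise from crossing the threshold. Segments
    where more than half the member bins deviate from the segment mean by
    over 4 robust SDs are forced neutral (the residual filter lifted to
    segment level), as are all segments on excluded chromosomes (chr19 by
    default).
    """
    baseline = _modal_baseline(segments) if recenter and segments else 0.0
    calls = []
    for seg in segments:
        dev = seg.mean_log2 - baseline
        se = (profile.residual_sd / np.sqrt(seg.n_bins)
              if profile.residual_sd > 0 else 0.0)
        state = STATE_NEUTRAL
        if dev >= gain_threshold and abs(dev) >= min_z * se:
            state = STATE_GAIN
        elif dev <= loss_threshold and abs(dev) >= min_z * se:
            state = STATE_LOSS
        if state != STATE_NEUTRAL and profile.residual_sd > 0 \
                and seg.bin_indices is not None:
            res = np.abs(profile.log2ratio[seg.bin_indices] - seg.mean_log2)
            frac = float((res > RESIDUAL_SD_FACTOR * profile.residual_sd).mean())
            if frac > max_outlier_fraction:
                state = STATE_NEUTRAL
        if seg.chrom in excluded_chroms:
            state = STATE_NEUTRAL
        calls.append(CNACall(
            cell_id=seg.cell_id, chrom=seg.chrom, start=seg.start,
            end=seg.end, n_bins=seg.n_bins, mean_log2=seg.mean_log2,
            state=state))
    return calls


def classify_aberrant(calls: list[CNACall],
                      single_mb: float = ABERRANT_SINGLE_MB,
                      cumulative_mb: float = ABERRANT_CUMULATIVE_MB) -> bool:
    """A cell is aberrant when any gained/lost region exceeds 12.5 Mb, or the
    gained/lost regions together exceed 37.5 Mb."""
    lengths = [c.length_mb for c in calls if c.state != STATE_NEUTRAL]
    return any(l > single_mb for l in lengths) or sum(lengths) > cumulative_mb


def count_cna(calls: list[CNACall]) -> tuple[int, int]:
    """(number of gain calls, number of loss calls)."""
    n_gain = sum(1 for c in calls if c.state == STATE_GAIN)
    n_loss = sum(1 for c in calls if c.state == STATE_LOSS)
    return n_gain, n_loss


def cna_profile(cell_id: str, calls: list[CNACall]) -> CNAProfile:
    n_gain, n_loss = count_cna(calls)
    return CNAProfile(cell_id=cell_id, calls=calls, n_gain=n_gain,
                      n_loss=n_loss, aberrant=classify_aberrant(calls))


# ---------------------------------------------------------------------------
# SEG / TSV I/O  (SEG is 1-based inclusive; internal coordinates 0-based)
# ---------------------------------------------------------------------------

def segments_to_seg(segments: list[Segment] | list[CNACall], path) -> None:
    rows = [{
        "sample": s.cell_id, "chrom": s.chrom, "start": s.start + 1,
        "end": s.end, "n_bins": s.n_bins, "mean_log2": s.mean_log2,
    } for s in segments]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_bins", "mean_log2"]).to_csv(
        path, sep="\t", index=False)


def calls_to_tsv(calls: list[CNACall], path) -> None:
    rows = [{
        "sample": c.cell_id, "chrom": c.chrom, "start": c.start + 1,
        "end": c.end, "n_bins": c.n_bins, "mean_log2": c.mean_log2,
        "state": c.state, "length_mb": c.length_mb,
    } for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def calls_from_tsv(path) -> dict[str, list[CNACall]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[CNACall]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["sample"]), []).append(CNACall(
            cell_id=str(r["sample"]), chrom=str(r["chrom"]),
            start=int(r["start"]) - 1, end=int(r["end"]),
            n_bins=int(r["n_bins"]), mean_log2=float(r["mean_log2"]),
            state=str(r["state"])))
    return out
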