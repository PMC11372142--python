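"""Large-scale transition (LST) scoring and reproducibility statistics.

An LST is a chromosomal break between two adjacent copy-number regions each
spanning at least 10 Mb. The per-cell LST count is the chromosomal-
instability metric; cells are classified LST-high when the count reaches 3.
Counting operates on called copy-number states (loss/neutral/gain), after
merging away sub-threshold segments, which stabilises the tally under
single-cell noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import CNACall, STATE_GAIN, STATE_LOSS, STATE_NEUTRAL

LST_MIN_SEGMENT_MB = 10.0
LST_HIGH_THRESHOLD = 3
SMOOTH_MIN_SIZE_MB = 3.0

_STATE_VALUE = {STATE_LOSS: -1, STATE_NEUTRAL: 0, STATE_GAIN: 1}
_VALUE_STATE = {v: k for k, v in _STATE_VALUE.items()}


@dataclass(frozen=True)
class StateSegment:
    """A CN-state run used for LST counting (coordinates in bp)."""

    chrom: str
    start: int
    end: int
    state: str

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class LSTResult:
    cell_id: str
    lst: int
    lst_class: str  # "low" | "high"


def smooth_segments(calls: list[CNACall] | list[StateSegment],
                    min_size_mb: float = SMOOTH_MIN_SIZE_MB
                    ) -> list[StateSegment]:
    """Merge away interior segments shorter than ``min_size_mb``.

    Repeatedly the shortest sub-threshold segment is absorbed into the
    neighbor whose CN state is numerically closer (loss=-1, neutral=0,
    gain=+1; ties go left); equal-state neighbors are then coalesced.
    ``min_size_mb = 0`` disables merging (coalescing still applies). A
    segment that is an entire chromosome is never removed.
    """
    out: list[StateSegment] = []
    by_chrom: dict[str, list[list]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(
            [c.start, c.end, _STATE_VALUE[c.state]])
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s[0])
        while len(segs) > 1:
            lengths = [(s[1] - s[0]) / 1e6 for s in segs]
            order = sorted(range(len(segs)), key=lambda i: lengths[i])
            i = order[0]
            if lengths[i] >= min_size_mb:
                break
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if left is not None and right is not None:
                dl = abs(segs[i][2] - left[2])
                dr = abs(segs[i][2] - right[2])
                target = left if dl <= dr else right
            else:
                target = left if left is not None else right
            if target is left:
                target[1] = segs[i][1]
            else:
                target[0] = segs[i][0]
            segs.pop(i)
        # coalesce equal-state neighbors
        merged = [segs[0]]
        for s in segs[1:]:
            if s[2] == merged[-1][2]:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        out.extend(StateSegment(chrom, s[0], s[1], _VALUE_STATE[s[2]])
                   for s in merged)
    return out


def count_lst(smoothed: list[StateSegment],
              centromeres: dict[str, int] | None = None,
              min_segment_mb: float = LST_MIN_SEGMENT_MB) -> int:
    """Tabulate large-scale transitions.

    Within each block (whole chromosome by default; p/q arm when a
    centromere position is supplied for that chromosome), every adjacent
    pair of segments with different CN state counts as one LST when BOTH
    segments span at least ``min_segment_mb``. Breaks are never counted
    across block boundaries.
    """
    total = 0
    by_chrom: dict[str, list[StateSegment]] = {}
    for s in smoothed:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        cen = None if centromeres is None else centromeres.get(chrom)
        blocks: list[list[StateSegment]] = []
        if cen is None:
            blocks.append(segs)
        else:
            p_arm, q_arm = [], []
            for s in segs:
                if s.end <= cen:
                    p_arm.append(s)
                elif s.start >= cen:
                    q_arm.append(s)
                else:  # straddles the centromere: split
                    p_arm.append(StateSegment(chrom, s.start, cen, s.state))
                    q_arm.append(StateSegment(chrom, cen, s.end, s.state))
            blocks.extend([p_arm, q_arm])
        for block in blocks:
            for a, b in zip(block[:-1], block[1:]):
                if (a.state != b.state
                        and a.length_mb >= min_segment_mb
                        and b.length_mb >= min_segment_mb):
                    total += 1
    return total


def classify_lst(lst: int, threshold: int = LST_HIGH_THRESHOLD) -> str:
    """LST-high when the count reaches the threshold (default 3), else low."""
    if lst < 0:
        raise ValueError("LST count cannot be negative")
    return "high" if lst >= threshold else "low"


def lst_result(cell_id: str, calls: list[CNACall],
               min_size_mb: float = SMOOTH_MIN_SIZE_MB,
               centromeres: dict[str, int] | None = None,
               threshold: int = LST_HIGH_THRESHOLD) -> LSTResult:
    """Full per-cell LST computation: smooth, count, classify."""
    n = count_lst(smooth_segments(calls, min_size_mb), centromeres)
    return LSTResult(cell_id=cell_id, lst=n, lst_class=classify_lst(n, threshold))


# ---------------------------------------------------------------------------
# Reproducibility statistics (cell-line replicate design)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReproStats:
    """Replicate summary for one group: mean, sample SD, CV = SD/mean, and a
    one-sample two-sided t-test against an explicit reference value."""

    label: str
    n: int
    mean: float
    sd: float
    cv: float
    t_p: float
    cv_defined: bool = True


def _one_sample_p(mean: float, sd: float, n: int, reference: float) -> float:
    if n < 2:
        return float("nan")
    if sd == 0:
        return 1.0 if mean == reference else float(np.finfo(float).tiny)
    t = (mean - reference) / (sd / np.sqrt(n))
    return float(2 * stats.t.sf(abs(t), df=n - 1))


def repro_stats_from_summary(label: str, n: int, mean: float, sd: float,
                             reference: float | None = None) -> ReproStats:
    """Build replicate statistics from a printed summary (n, mean, SD)."""
    cv_defined = mean != 0
    cv = sd / mean if cv_defined else float("nan")
    p = float("nan") if reference is None else _one_sample_p(mean, sd, n, reference)
    return ReproStats(label=label, n=n, mean=mean, sd=sd, cv=cv, t_p=p,
                      cv_defined=cv_defined)


def repro_stats(groups: dict[str, list[float]],
                reference: float | None = None) -> list[ReproStats]:
    """Per-group mean, sample SD (n-1 denominator), CV, and a one-sample
    t-test of the group mean against ``reference`` (default: the grand mean
    pooled over all values)."""
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs n >= 2")
    if reference is None:
        allvals = np.concatenate([np.asarray(v, float) for v in groups.values()])
        reference = float(allvals.mean())
    out = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        out.append(repro_stats_from_summary(label, len(v), mean, sd, reference))
    return out


def repro_table(stats_list: list[ReproStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.label, "n": s.n, "mean": s.mean, "sd": s.sd,
        "p": s.t_p, "cv": s.cv if s.cv_defined else "",
    } for s in stats_list])


# ---------------------------------------------------------------------------
# Cohort distribution summary
# ---------------------------------------------------------------------------

def lst_distribution_summary(results: list[LSTResult] | list[int]) -> dict:
    """Median / range / mean of per-cell LST counts plus a unit-bin histogram
    table (the cohort-distribution figure as numbers)."""
    values = [r.lst if isinstance(r, LSTResult) else int(r) for r in results]
    if not values:
        raise ValueError("no LST results to summarise")
    v = np.sort(np.asarray(values))
    hist = pd.Series(v).value_counts().sort_index()
    return {
        "n": len(v),
        "median": float(np.median(v)),
        "min": int(v[0]),
        "max": int(v[-1]),
        "mean": float(v.mean()),
        "histogram": pd.DataFrame({"lst": hist.index.to_numpy(),
                                   "n_cells": hist.to_numpy()}),
    }
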