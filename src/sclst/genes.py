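"""Gene-level CNA annotation, HRD-loss flags, group comparisons, and
over-representation analysis on the panel universe.

The cells x genes matrix (entries -1/0/+1) is the substrate of both the
heatmap-style reporting and the chromosomal-instability classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenePanel
from .pipeline import CNACall, STATE_GAIN, STATE_LOSS

log = logging.getLogger(__name__)

HRD_LOSS_GENES = ("RAD51", "BLM", "WRN")

_STATE_VALUE = {STATE_LOSS: -1, STATE_GAIN: 1}


def annotate_genes(calls_by_cell: dict[str, list[CNACall]],
                   panel: GenePanel) -> pd.DataFrame:
    """Project per-cell CNA calls onto the gene panel.

    Each gene takes the state of the call covering the majority of its
    length (ties broken by the call with the larger |mean log2|): gain ->
    +1, loss -> -1, neutral -> 0. Genes with no overlapping call (e.g. a
    chromosome absent from the calls) are 0 with a logged warning.

    Returns a cells x genes DataFrame of int8 in {-1, 0, +1}.
    """
    symbols = panel.symbols
    matrix = pd.DataFrame(0, index=list(calls_by_cell), columns=symbols,
                          dtype=np.int8)
    for cell_id, calls in calls_by_cell.items():
        for _, g in panel.table.iterrows():
            best_ov, best_abs, best_state = 0, -1.0, 0
            for c in calls:
                if c.chrom != g["chrom"]:
                    continue
                ov = min(c.end, g["end"]) - max(c.start, g["start"])
                if ov <= 0:
                    continue
                if ov > best_ov or (ov == best_ov
                                    and abs(c.mean_log2) > best_abs):
                    best_ov = ov
                    best_abs = abs(c.mean_log2)
                    best_state = _STATE_VALUE.get(c.state, 0)
            if best_ov == 0:
                log.warning("gene %s (%s) has no overlapping call in %s; "
                            "state set to 0", g["symbol"], g["chrom"], cell_id)
            matrix.loc[cell_id, g["symbol"]] = best_state
    return matrix


def hrd_loss_flags(matrix: pd.DataFrame,
                   genes: tuple[str, ...] = HRD_LOSS_GENES) -> pd.Series:
    """Per-cell flag: copy loss in any of RAD51, BLM, WRN."""
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise ValueError(f"panel lacks HRD loss genes: {missing}")
    return (matrix[list(genes)] == -1).any(axis=1)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test (point-probability summation convention):
    p is the sum of probabilities of all tables, with the observed margins,
    no more probable than the observed one. Returns (odds_ratio, p); the
    odds ratio is the unconditional ad/bc with infinity when bc = 0."""
    table = np.asarray(table, dtype=np.int64)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def compare_groups(lst_classes: pd.Series, cna_counts: pd.Series,
                   flags: pd.Series) -> dict:
    """Compare LST-high vs LST-low cells.

    Continuous: per-class median and mean CNA counts with a two-sided
    two-sample t-test. Categorical: 2x2 Fisher exact (two-sided) of the
    HRD-loss flag against the class, with the odds ratio. All counts and
    whole-percent prevalences are echoed in the report.
    """
    classes = lst_classes.astype(str)
    report: dict = {"groups": {}}
    for cls in ("high", "low"):
        cells = classes[classes == cls].index
        if len(cells) == 0:
            raise ValueError(f"no cells in LST-{cls} class")
        counts = cna_counts.loc[cells].astype(float)
        f = flags.loc[cells].astype(bool)
        report["groups"][cls] = {
            "n": int(len(cells)),
            "median_cna": float(np.median(counts)),
            "mean_cna": float(counts.mean()),
            "n_hrd_loss": int(f.sum()),
            "pct_hrd_loss": int(round(100.0 * f.sum() / len(cells))),
        }
    hi = cna_counts.loc[classes[classes == "high"].index].astype(float)
    lo = cna_counts.loc[classes[classes == "low"].index].astype(float)
    if hi.nunique() <= 1 and lo.nunique() <= 1 and hi.mean() == lo.mean():
        t_p = 1.0  # identical flat groups: no evidence either way
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_p = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
    g = report["groups"]
    table = [[g["high"]["n_hrd_loss"], g["high"]["n"] - g["high"]["n_hrd_loss"]],
             [g["low"]["n_hrd_loss"], g["low"]["n"] - g["low"]["n_hrd_loss"]]]
    odds, fisher_p = fisher_exact_2x2(table)
    report["cna_t_p"] = t_p
    report["hrd_table"] = table
    report["hrd_odds_ratio"] = odds
    report["hrd_fisher_p"] = fisher_p
    return report


# ---------------------------------------------------------------------------
# Over-representation analysis (panel universe)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORAResult:
    name: str
    k: int            # altered genes in the set
    K: int            # set size
    n: int            # altered genes in the universe
    N: int            # universe (panel) size
    odds_ratio: float
    p: float
    p_adj: float


def altered_genes(matrix: pd.DataFrame, lst_classes: pd.Series,
                  min_fraction: float = 0.5) -> set[str]:
    """Genes counted as altered for enrichment: non-neutral in more than
    ``min_fraction`` of LST-high cells."""
    hi = matrix.loc[lst_classes[lst_classes.astype(str) == "high"].index]
    if len(hi) == 0:
        return set()
    frac = (hi != 0).mean(axis=0)
    return set(frac.index[frac > min_fraction])


def ora(matrix: pd.DataFrame, lst_classes: pd.Series,
        genesets: dict[str, list[str]],
        min_fraction: float = 0.5) -> list[ORAResult]:
    """Fisher-exact over-representation of altered genes in each gene set,
    against the panel as the universe, Benjamini-Hochberg adjusted across
    sets. Sets are restricted to panel genes; empty sets are an error."""
    universe = list(matrix.columns)
    altered = altered_genes(matrix, lst_classes, min_fraction)
    raw = []
    for name, members in genesets.items():
        members = [g for g in members if g in universe]
        if not members:
            raise ValueError(f"gene set {name!r} has no genes in the panel")
        k = len(altered & set(members))
        K = len(members)
        n = len(altered)
        N = len(universe)
        table = [[k, K - k], [n - k, (N - K) - (n - k)]]
        odds, p = fisher_exact_2x2(table)
        raw.append((name, k, K, n, N, odds, p))
    adj = multipletests([r[6] for r in raw], method="fdr_bh")[1] if raw else []
    return [ORAResult(*r, p_adj=float(a)) for r, a in zip(raw, adj)]


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format view of the gene-CNA matrix (cell_id, gene, state) for
    heatmap tooling."""
    long = matrix.reset_index().melt(id_vars=matrix.index.name or "index",
                                     var_name="gene", value_name="state")
    return long.rename(columns={matrix.index.name or "index": "cell_id"})


def load_gmt(path) -> dict[str, list[str]]:
    """GMT-style gene sets: one set per line, tab-separated
    (name, description, symbols...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# Top-altered-genes report
# ---------------------------------------------------------------------------

def top_altered_genes(matrix: pd.DataFrame, panel: GenePanel | None = None,
                      k: int = 50) -> pd.DataFrame:
    """Rank genes by alteration frequency (fraction of cells with a
    non-neutral state), ties broken alphabetically; unaltered genes are
    dropped. Includes per-gene gain/loss cell counts and, when a panel is
    supplied, the chromosome label."""
    freq = (matrix != 0).mean(axis=0)
    gains = (matrix == 1).sum(axis=0)
    losses = (matrix == -1).sum(axis=0)
    df = pd.DataFrame({"gene": freq.index, "frequency": freq.to_numpy(),
                       "n_gain": gains.to_numpy(), "n_loss": losses.to_numpy()})
    df = df[df["frequency"] > 0]
    if panel is not None:
        chrom = panel.table.set_index("symbol")["chrom"]
        df["chrom"] = df["gene"].map(chrom)
    df = df.sort_values(["frequency", "gene"], ascending=[False, True],
                        kind="mergesort").head(k).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
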