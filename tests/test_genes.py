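"""Gene-level CNA projection, HRD-loss flags, Fisher statistics with an
enumeration oracle, over-representation analysis, top-gene ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sclst import (
    GenePanel,
    annotate_genes,
    compare_groups,
    fisher_exact_2x2,
    hrd_loss_flags,
    ora,
    top_altered_genes,
)

from conftest import make_call


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probability of every table with the same margins whose probability does
    not exceed the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def panel_from_rows(rows):
    return GenePanel(pd.DataFrame(
        rows, columns=["symbol", "chrom", "start", "end", "category"]))


class TestAnnotateGenes:
    panel = panel_from_rows([
        ("G1", "chr1", 10_000_000, 10_100_000, "HRD"),
        ("G2", "chr1", 50_000_000, 60_000_000, "TNBC_driver"),
        ("G19", "chr19", 1_000_000, 2_000_000, "TNBC_driver"),
    ])

    def test_gene_inside_loss_segment(self):
        calls = {"c1": [make_call("chr1", 0, 30, "loss"),
                        make_call("chr1", 30, 100, "neutral")]}
        m = annotate_genes(calls, self.panel)
        assert m.loc["c1", "G1"] == -1
        assert m.loc["c1", "G2"] == 0

    def test_chr19_gene_neutral_because_calls_forced_neutral_upstream(self):
        # chr19 segments arrive as neutral from call_states
        calls = {"c1": [make_call("chr19", 0, 59, "neutral", mean=-1.0)]}
        m = annotate_genes(calls, self.panel)
        assert m.loc["c1", "G19"] == 0

    def test_majority_overlap_rule_against_interval_oracle(self):
        # gene G2 spans 50-60 Mb; split 60/40 between neutral and gain
        calls = {"c1": [make_call("chr1", 0, 56, "neutral"),
                        make_call("chr1", 56, 100, "gain")]}
        m = annotate_genes(calls, self.panel)
        # oracle: overlap lengths
        ov_neutral = 56e6 - 50e6
        ov_gain = 60e6 - 56e6
        assert ov_neutral > ov_gain
        assert m.loc["c1", "G2"] == 0

    def test_tie_broken_by_larger_absolute_mean(self):
        calls = {"c1": [make_call("chr1", 45, 55, "neutral", mean=0.01),
                        make_call("chr1", 55, 65, "gain", mean=0.9)]}
        m = annotate_genes(calls, self.panel)  # 5 Mb overlap each
        assert m.loc["c1", "G2"] == 1

    def test_gene_with_no_overlapping_call_is_zero(self):
        calls = {"c1": [make_call("chr1", 0, 100, "neutral")]}
        m = annotate_genes(calls, self.panel)
        assert m.loc["c1", "G19"] == 0

    def test_matrix_is_deterministic(self):
        calls = {"c1": [make_call("chr1", 0, 30, "loss"),
                        make_call("chr1", 30, 100, "gain")]}
        a = annotate_genes(calls, self.panel)
        b = annotate_genes(calls, self.panel)
        pd.testing.assert_frame_equal(a, b)


class TestHRDFlags:
    def make_matrix(self, rad51=0, blm=0, wrn=0):
        return pd.DataFrame({"RAD51": [rad51], "BLM": [blm], "WRN": [wrn],
                             "TP53": [0]}, index=["c1"])

    def test_any_single_loss_sets_flag(self):
        assert hrd_loss_flags(self.make_matrix(rad51=-1)).loc["c1"]

    def test_gains_do_not_set_flag(self):
        assert not hrd_loss_flags(self.make_matrix(blm=1, wrn=1)).loc["c1"]

    def test_missing_gene_is_explicit_error(self):
        m = pd.DataFrame({"RAD51": [0]}, index=["c1"])
        with pytest.raises(ValueError, match="BLM"):
            hrd_loss_flags(m)


class TestFisher:
    def test_matches_enumeration_oracle_on_all_small_tables(self):
        # every 2x2 table with total <= 30 (hence every margin <= 30)
        for n in range(0, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        _, p = fisher_exact_2x2(table)
                        assert p == pytest.approx(
                            fisher_enumeration_oracle(table), abs=1e-12)

    def test_extreme_table(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(fisher_enumeration_oracle([[10, 0], [0, 10]]),
                                  abs=1e-12)


class TestCompareGroups:
    def _inputs(self, n_high=22, n_low=13, k_high=13, k_low=4):
        cells = [f"c{i}" for i in range(n_high + n_low)]
        classes = pd.Series(["high"] * n_high + ["low"] * n_low, index=cells)
        flags = pd.Series([True] * k_high + [False] * (n_high - k_high)
                          + [True] * k_low + [False] * (n_low - k_low),
                          index=cells)
        counts = pd.Series([22] * n_high + [13] * n_low, index=cells,
                           dtype=float)
        return classes, counts, flags

    def test_printed_count_percentages(self):
        classes, counts, flags = self._inputs()
        rep = compare_groups(classes, counts, flags)
        assert rep["groups"]["high"]["pct_hrd_loss"] == 59  # 13/22
        assert rep["groups"]["low"]["pct_hrd_loss"] == 31   # 4/13
        assert rep["groups"]["high"]["n_hrd_loss"] == 13
        assert rep["hrd_table"] == [[13, 9], [4, 9]]

    def test_identical_groups_give_p_one(self):
        cells = [f"c{i}" for i in range(8)]
        classes = pd.Series(["high"] * 4 + ["low"] * 4, index=cells)
        counts = pd.Series([10.0] * 8, index=cells)
        flags = pd.Series([True, False, True, False] * 2, index=cells)
        rep = compare_groups(classes, counts, flags)
        assert rep["cna_t_p"] == pytest.approx(1.0)
        assert rep["hrd_fisher_p"] == pytest.approx(1.0)

    def test_median_cna_reported_per_class(self):
        classes, counts, flags = self._inputs()
        rep = compare_groups(classes, counts, flags)
        assert rep["groups"]["high"]["median_cna"] == 22
        assert rep["groups"]["low"]["median_cna"] == 13

    def test_empty_class_rejected(self):
        cells = ["c1", "c2"]
        classes = pd.Series(["high", "high"], index=cells)
        with pytest.raises(ValueError):
            compare_groups(classes, pd.Series([1.0, 2.0], index=cells),
                           pd.Series([False, False], index=cells))


class TestORA:
    def _matrix(self, rng, n_cells=30, n_genes=20, hot=(), p_hot=0.8,
                p_bg=0.1):
        genes = [f"G{i}" for i in range(n_genes)]
        X = np.zeros((n_cells, n_genes), dtype=int)
        for j, g in enumerate(genes):
            p = p_hot if g in hot else p_bg
            X[:, j] = np.where(rng.uniform(size=n_cells) < p, -1, 0)
        idx = [f"c{i}" for i in range(n_cells)]
        return (pd.DataFrame(X, columns=genes, index=idx),
                pd.Series(["high"] * n_cells, index=idx))

    def test_set_of_all_altered_genes_ranks_first(self):
        rng = np.random.default_rng(0)
        m, cls = self._matrix(rng, hot=("G0", "G1", "G2"))
        res = ora(m, cls, {"hot": ["G0", "G1", "G2"],
                           "cold": ["G10", "G11", "G12"]})
        by_name = {r.name: r for r in res}
        assert by_name["hot"].p < by_name["cold"].p
        assert by_name["hot"].k == 3

    def test_disjoint_set_k_zero(self):
        rng = np.random.default_rng(1)
        m, cls = self._matrix(rng, hot=("G0",))
        res = ora(m, cls, {"cold": ["G10", "G11"]})
        assert res[0].k == 0
        _, p_expected = fisher_exact_2x2(
            [[0, 2], [res[0].n, (res[0].N - 2) - res[0].n]])
        assert res[0].p == pytest.approx(p_expected)

    def test_planted_set_ranks_first_across_seeds(self):
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            m, cls = self._matrix(rng, hot=("G0", "G1", "G2"))
            res = ora(m, cls, {"A": ["G0", "G1", "G2"],
                               "B": ["G5", "G6", "G7"],
                               "C": ["G10", "G11", "G12"]})
            best = min(res, key=lambda r: (r.p_adj, r.p))
            wins += best.name == "A"
        assert wins >= int(0.9 * n_seeds)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        m, cls = self._matrix(rng, hot=("G0", "G1"))
        res = ora(m, cls, {"A": ["G0", "G1"], "B": ["G5"], "C": ["G9"]})
        for r in res:
            assert r.p_adj >= r.p - 1e-15

    def test_empty_gene_set_rejected(self):
        rng = np.random.default_rng(4)
        m, cls = self._matrix(rng)
        with pytest.raises(ValueError, match="no genes"):
            ora(m, cls, {"empty": ["NOT_A_GENE"]})


class TestTopAlteredGenes:
    def test_all_zero_matrix_empty_ranking(self):
        m = pd.DataFrame(0, index=["c1", "c2"], columns=["G1", "G2"])
        assert len(top_altered_genes(m)) == 0

    def test_universally_altered_gene_ranks_first(self):
        m = pd.DataFrame({"G1": [1, 1, 1], "G2": [0, -1, 0]},
                         index=["c1", "c2", "c3"])
        out = top_altered_genes(m)
        assert out.iloc[0]["gene"] == "G1"
        assert out.iloc[0]["frequency"] == 1.0
        assert out.iloc[0]["n_gain"] == 3

    def test_ranking_matches_independent_sort(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.choice([-1, 0, 1], size=(40, 25)),
                         columns=[f"G{i:02d}" for i in range(25)],
                         index=[f"c{i}" for i in range(40)])
        out = top_altered_genes(m, k=25)
        freq = {g: float((m[g] != 0).mean()) for g in m.columns}
        expected = sorted((g for g in m.columns if freq[g] > 0),
                          key=lambda g: (-freq[g], g))
        assert out["gene"].tolist() == expected
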