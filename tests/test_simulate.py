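"""Synthetic data generator: truth construction, oracles, forward model."""

import numpy as np
import pandas as pd
import pytest

from sclst import (
    CNEvent,
    SimConfig,
    emit_bin_counts,
    profile_from_events,
    simulate_clone_replicates,
    simulate_cohort,
    simulate_truth,
    synthetic_panel,
    toy_genome,
)
from sclst.simulate import (
    aberrant_from_truth,
    lst_from_truth,
    truth_segments,
    truth_state_segments,
)


# ---------------------------------------------------------------------------
# Independent truth-LST oracle (state collapse -> snap -> smooth -> count)
# ---------------------------------------------------------------------------

def oracle_true_lst(segments: pd.DataFrame, ploidy=2, snap=500_000,
                    smooth_mb=3.0, min_mb=10.0):
    total = 0
    for chrom, sub in segments.groupby("chrom", sort=False):
        # state runs
        runs = []
        for _, s in sub.iterrows():
            st = int(np.sign(s["cn"] - ploidy))
            if runs and runs[-1][2] == st:
                runs[-1][1] = s["end"]
            else:
                runs.append([s["start"], s["end"], st])
        # snap interior boundaries
        bounds = [0] + [int(round(r[1] / snap)) * snap for r in runs[:-1]] \
            + [runs[-1][1]]
        snapped = []
        for r, lo, hi in zip(runs, bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            if snapped and snapped[-1][2] == r[2]:
                snapped[-1][1] = hi
            else:
                snapped.append([lo, hi, r[2]])
        runs = snapped
        # smoothing: shortest-first merge into the closer-state neighbor
        while len(runs) > 1:
            lengths = [(r[1] - r[0]) / 1e6 for r in runs]
            i = int(np.argmin(lengths))
            if lengths[i] >= smooth_mb:
                break
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i < len(runs) - 1 else None
            if left is not None and right is not None:
                target = left if abs(runs[i][2] - left[2]) <= \
                    abs(runs[i][2] - right[2]) else right
            else:
                target = left if left is not None else right
            if target is left:
                target[1] = runs[i][1]
            else:
                target[0] = runs[i][0]
            runs.pop(i)
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        for a, b in zip(merged, merged[1:]):
            if (a[2] != b[2] and a[1] - a[0] >= min_mb * 1e6
                    and b[1] - b[0] >= min_mb * 1e6):
                total += 1
    return total


class TestTruthConstruction:
    def test_flat_diploid_truth(self, genome3):
        cfg = SimConfig(n_cells=3, n_clonal_events=0, n_private_events=0,
                        seed=0)
        panel = synthetic_panel(genome3, 10, np.random.default_rng(0))
        for p in simulate_truth(cfg, genome3, panel):
            assert p.true_lst == 0
            assert not p.true_aberrant
            assert (p.true_gene_states == 0).all()
            assert (p.segments["cn"] == 2).all()

    def test_single_interior_gain_gives_two_lsts(self, genome3):
        p = profile_from_events(
            "c", [CNEvent("chr1", 40_000_000, 55_000_000, +1)], genome3)
        assert p.true_lst == 2
        assert p.true_aberrant  # 15 Mb > 12.5 Mb

    def test_overlapping_events_compose_additively_with_floor(self, genome3):
        events = [CNEvent("chr1", 10_000_000, 30_000_000, -1),
                  CNEvent("chr1", 20_000_000, 40_000_000, -2)]
        segs = truth_segments(genome3, events)
        sub = segs[segs["chrom"] == "chr1"]
        # 20-30 Mb has delta -3 on ploidy 2 -> floored at 0
        row = sub[(sub["start"] == 20_000_000)]
        assert row["cn"].iloc[0] == 0

    def test_event_count_matches_poisson_mean(self, genome3):
        cfg = SimConfig(n_cells=200, n_clonal_events=0, n_private_events=3.0,
                        seed=9)
        profiles = simulate_truth(cfg, genome3)
        counts = np.array([len(p.events) for p in profiles])
        se = np.sqrt(3.0 / len(counts))
        assert abs(counts.mean() - 3.0) <= 3 * se

    def test_oversized_event_range_rejected(self, genome3):
        cfg = SimConfig(n_cells=1, event_length_range=(2_000_000_000,
                                                       3_000_000_000))
        with pytest.raises(ValueError, match="longest chromosome"):
            simulate_truth(cfg, genome3)

    def test_true_lst_matches_independent_oracle(self, genome3):
        cfg = SimConfig(n_cells=50, seed=123)
        for p in simulate_truth(cfg, genome3):
            assert p.true_lst == oracle_true_lst(p.segments)

    def test_true_aberrant_matches_direct_predicate(self, genome3):
        cfg = SimConfig(n_cells=30, seed=77)
        for p in simulate_truth(cfg, genome3):
            dev = p.segments[p.segments["cn"] != 2]
            mb = (dev["end"] - dev["start"]) / 1e6
            assert p.true_aberrant == bool(
                (mb > 12.5).any() or mb.sum() > 37.5)

    def test_gene_states_consistent_with_events(self, genome3):
        panel = synthetic_panel(genome3, 20, np.random.default_rng(3))
        cfg = SimConfig(n_cells=10, seed=5)
        for p in simulate_truth(cfg, genome3, panel):
            for _, g in panel.table.iterrows():
                state = p.true_gene_states[g["symbol"]]
                assert state in (-1, 0, 1)


class TestEmission:
    def test_flat_uniform_expectation_and_exact_depth(self):
        from sclst import annotate_gc_mappability, build_bin_grid
        from sclst.simulate import bin_copy_number, gc_bias_curve

        genome = toy_genome(n_chroms=1, length=1_000_000_000)
        grid = build_bin_grid(genome, 500_000)  # 2000 equal bins
        annotate_gc_mappability(grid)  # constant gc -> constant bias
        cfg = SimConfig(n_cells=1, n_clonal_events=0, n_private_events=0,
                        depth=1_000_000, wga_dispersion=0.0, dropout_rate=0.0,
                        seed=4)
        truth = profile_from_events("c", [], genome)
        cn = bin_copy_number(truth, grid)
        w = cn * gc_bias_curve(grid.bins["gc"].to_numpy(), cfg.gc_bias_strength)
        expected = cfg.depth * w / w.sum()
        assert np.allclose(expected, 500.0)  # 1e6 reads over 2000 bins
        bc = emit_bin_counts(truth, grid, cfg)
        assert bc.total_reads == cfg.depth  # multinomial conserves reads

    def test_cn4_vs_cn2_expected_ratio_two(self, genome3, grid3):
        from sclst.simulate import bin_copy_number, gc_bias_curve

        truth = profile_from_events(
            "c", [CNEvent("chr1", 0, 50_000_000, +2)], genome3)
        cn = bin_copy_number(truth, grid3)
        gc = grid3.bins["gc"].to_numpy()
        w = cn * gc_bias_curve(gc, 0.0)
        ratio = w[50] / w[250]  # CN4 bin vs CN2 bin, same (zero) bias
        assert ratio == pytest.approx(2.0)

    def test_wga_dispersion_matches_compound_cv_formula(self, genome3):
        from sclst import annotate_gc_mappability, build_bin_grid

        grid = build_bin_grid(genome3, 500_000)
        annotate_gc_mappability(grid)
        sigma, depth = 0.3, 1_000_000
        cfg = SimConfig(n_cells=100, n_clonal_events=0, n_private_events=0,
                        depth=depth, wga_dispersion=sigma, dropout_rate=0.0,
                        gc_bias_strength=0.0, seed=21)
        profiles, counts = simulate_cohort(cfg, genome3, grid)
        mu = depth / len(grid)
        cv_expected = np.sqrt(np.exp(sigma**2) * (1 + 1 / mu) - 1)
        cvs = [bc.counts.std() / bc.counts.mean() for bc in counts]
        assert np.mean(cvs) == pytest.approx(cv_expected, rel=0.10)
        assert np.mean(cvs) > 1 / np.sqrt(mu)  # exceeds Poisson-only CV

    def test_total_reads_within_5pct_of_depth_under_distortion(self, genome3,
                                                               grid3):
        cfg = SimConfig(n_cells=100, depth=1_000_000, seed=33)
        _, counts = simulate_cohort(cfg, genome3, grid3)
        mean_total = np.mean([bc.total_reads for bc in counts])
        assert abs(mean_total / cfg.depth - 1) < 0.05

    def test_dropout_creates_contiguous_low_regions(self, genome3):
        from sclst import annotate_gc_mappability, build_bin_grid

        grid = build_bin_grid(genome3, 500_000)
        annotate_gc_mappability(grid)
        cfg = SimConfig(n_cells=1, n_clonal_events=0, n_private_events=0,
                        wga_dispersion=0.0, dropout_rate=0.05,
                        gc_bias_strength=0.0, seed=8)
        truth = profile_from_events("c", [], genome3)
        bc = emit_bin_counts(truth, grid, cfg)
        low = bc.counts < 0.3 * np.median(bc.counts)
        assert 0.02 <= low.mean() <= 0.10  # ~5% of bins depressed

    def test_all_unusable_grid_rejected(self, genome3):
        from sclst import annotate_gc_mappability, build_bin_grid

        grid = build_bin_grid(genome3, 500_000)
        annotate_gc_mappability(grid, map_track=np.zeros(len(grid)))
        truth = profile_from_events("c", [], genome3)
        with pytest.raises(ValueError, match="usable"):
            emit_bin_counts(truth, grid, SimConfig(n_cells=1))


class TestDeterminismAndClones:
    def test_same_seed_reproduces_cohort_exactly(self, genome3, grid3):
        cfg = SimConfig(n_cells=4, seed=55)
        p1, c1 = simulate_cohort(cfg, genome3, grid3)
        p2, c2 = simulate_cohort(cfg, genome3, grid3)
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a.segments, b.segments)
            assert a.true_lst == b.true_lst
        for a, b in zip(c1, c2):
            assert np.array_equal(a.counts, b.counts)

    def test_replicates_share_clonal_events(self, genome3):
        cfg = SimConfig(n_cells=1, n_clonal_events=4, n_private_events=1,
                        seed=10)
        pop = simulate_clone_replicates(cfg, genome3, None, n_replicates=5)
        for rep in pop.replicates:
            for e in pop.clonal_events:
                assert e in rep.events

    def test_no_private_events_means_identical_truth(self, genome3):
        cfg = SimConfig(n_cells=1, n_clonal_events=4, n_private_events=0,
                        seed=11)
        pop = simulate_clone_replicates(cfg, genome3, None, n_replicates=6)
        lsts = [r.true_lst for r in pop.replicates]
        assert len(set(lsts)) == 1  # replicate truth-LST SD is zero

    def test_single_replicate_rejected(self, genome3):
        with pytest.raises(ValueError):
            simulate_clone_replicates(SimConfig(n_cells=1), genome3, None, 1)
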