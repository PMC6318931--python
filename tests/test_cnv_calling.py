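import numpy as np
import pytest

import sspgds as s
from sspgds.cnv_calling import (
    CBSSegmenter,
    ChromCall,
    CnvCall,
    arraycgh_like_call,
    classify_segments,
    decide_implantable,
    permutation_p,
)
from sspgds.normalization import ReferencePanel

from ._oracles import exhaustive_best_arc


def fake_panel(grid, chrom_mean=1.0, chrom_sd=0.02):
    panel = ReferencePanel(grid)
    panel.n_controls_ = 5
    panel.mask_ = grid.masked.copy()
    panel.per_bin_mean_ = np.ones(grid.n_bins)
    panel.per_bin_sd_ = np.full(grid.n_bins, 0.1)
    panel.per_chrom_mean_ = {c: chrom_mean for c in grid.chroms}
    panel.per_chrom_sd_ = {c: chrom_sd for c in grid.chroms}
    return panel


class TestCallAneuploidy:
    def test_sample_at_panel_mean_is_all_disomy(self, toy_grid):
        panel = fake_panel(toy_grid)
        calls = s.call_aneuploidy(np.ones(toy_grid.n_bins), panel,
                                  min_chrom_sd=0.02)
        assert all(c.call == "disomy" and c.z == 0.0 for c in calls)

    def test_full_trisomy_z(self, toy_grid):
        ratio = np.ones(toy_grid.n_bins)
        ratio[toy_grid.chrom_slice("chr2")] = 1.5
        calls = s.call_aneuploidy(ratio, fake_panel(toy_grid),
                                  min_chrom_sd=0.02)
        by = {c.chrom: c for c in calls}
        assert by["chr2"].z == pytest.approx(25.0)
        assert by["chr2"].call == "trisomy"
        assert by["chr1"].call == "disomy"

    def test_mosaic_trisomy_z(self, toy_grid):
        # 0.3-mixing trisomy: expected ratio 0.3*1.5 + 0.7*1.0 = 1.15
        ratio = np.ones(toy_grid.n_bins)
        ratio[toy_grid.chrom_slice("chr3")] = 1.15
        calls = s.call_aneuploidy(ratio, fake_panel(toy_grid),
                                  min_chrom_sd=0.02)
        by = {c.chrom: c for c in calls}
        assert by["chr3"].z == pytest.approx(7.5)
        assert by["chr3"].call == "trisomy"

    def test_monosomy(self, toy_grid):
        ratio = np.ones(toy_grid.n_bins)
        ratio[toy_grid.chrom_slice("chr2")] = 0.5
        calls = s.call_aneuploidy(ratio, fake_panel(toy_grid),
                                  min_chrom_sd=0.02)
        assert {c.chrom: c.call for c in calls}["chr2"] == "monosomy"

    def test_sd_floor_suppresses_small_fluctuations(self, toy_grid):
        ratio = np.ones(toy_grid.n_bins)
        ratio[toy_grid.chrom_slice("chr2")] = 1.08  # z=4 at sd 0.02
        calls = s.call_aneuploidy(ratio, fake_panel(toy_grid),
                                  min_chrom_sd=0.035)
        assert {c.chrom: c.call for c in calls}["chr2"] == "disomy"


class TestAccumulate:
    def grid_pair(self):
        g20 = s.make_bins({"chr1": 20_000 * 100}, 20_000)
        return g20, g20.aggregate(25)

    def test_uniform_children(self):
        g20, g500 = self.grid_pair()
        prof = s.RatioProfile("x", np.ones(g20.n_bins),
                              np.zeros(g20.n_bins, bool))
        v, m = s.accumulate_to_superbins(prof, g20, g500)
        assert np.allclose(v, 1.0) and not m.any()

    def test_masked_children_excluded(self):
        g20, g500 = self.grid_pair()
        ratio = np.full(g20.n_bins, 1.5)
        mask = np.zeros(g20.n_bins, bool)
        mask[:5] = True  # 5 of the first superbin's 25 children
        ratio[mask] = np.nan
        v, m = s.accumulate_to_superbins(s.RatioProfile("x", ratio, mask),
                                         g20, g500)
        assert v[0] == pytest.approx(1.5) and not m[0]

    def test_mean_arithmetic(self):
        g20, g500 = self.grid_pair()
        ratio = np.ones(g20.n_bins)
        ratio[0] = 2.0  # children {1.0 x24, 2.0 x1} -> 1.04
        v, _ = s.accumulate_to_superbins(
            s.RatioProfile("x", ratio, np.zeros(g20.n_bins, bool)), g20, g500)
        assert v[0] == pytest.approx(1.04)

    def test_sparse_superbin_is_masked(self):
        g20, g500 = self.grid_pair()
        mask = np.zeros(g20.n_bins, bool)
        mask[:21] = True  # leaves 4 < 5 unmasked children in superbin 0
        ratio = np.where(mask, np.nan, 1.0)
        _, m = s.accumulate_to_superbins(s.RatioProfile("x", ratio, mask),
                                         g20, g500)
        assert m[0] and not m[1]

    def test_non_nested_grids_error(self):
        g20, _ = self.grid_pair()
        g_odd = s.make_bins({"chr1": 20_000 * 100}, 30_000)
        with pytest.raises(ValueError):
            s.accumulate_to_superbins(np.ones(g20.n_bins), g20, g_odd)


class TestCBS:
    def test_flat_noisy_track_is_one_segment(self):
        rng = np.random.default_rng(21)
        x = rng.normal(1.0, 0.1, 100)
        segs = CBSSegmenter().segment(x)
        assert segs == [(0, 100)]

    def test_single_step_track(self):
        rng = np.random.default_rng(22)
        x = np.r_[np.full(40, 1.0), np.full(20, 1.5), np.full(40, 1.0)]
        x += rng.normal(0, 0.05, 100)
        segs = CBSSegmenter().segment(x)
        assert len(segs) == 3
        (a0, a1), (b0, b1), (c0, c1) = segs
        assert abs(b0 - 40) <= 1 and abs(b1 - 60) <= 1

    def test_two_separated_steps(self):
        rng = np.random.default_rng(23)
        x = np.full(100, 1.0)
        x[20:30] = 1.5
        x[60:75] = 0.5
        x += rng.normal(0, 0.05, 100)
        segs = CBSSegmenter().segment(x)
        assert len(segs) == 5
        starts = [a for a, _ in segs]
        assert starts == sorted(starts)
        assert abs(segs[1][0] - 20) <= 1 and abs(segs[1][1] - 30) <= 1
        assert abs(segs[3][0] - 60) <= 1 and abs(segs[3][1] - 75) <= 1

    def test_permutation_split_mode_agrees_on_strong_step(self):
        rng = np.random.default_rng(24)
        x = np.r_[np.full(30, 1.0), np.full(15, 1.6), np.full(30, 1.0)]
        x += rng.normal(0, 0.05, 75)
        segs = CBSSegmenter(split_method="permutation", alpha_split=0.01,
                            n_split_perm=200, seed=5).segment(x)
        assert len(segs) == 3

    def test_short_track_single_segment(self, toy_grid):
        g500 = toy_grid.aggregate(25)
        values = np.ones(g500.n_bins)
        out = s.cbs_segment(values, np.zeros(g500.n_bins, bool), g500)
        for chrom, segs in out.items():
            assert len(segs) == 1 and segs[0]["unsplittable"]

    def test_breakpoints_match_exhaustive_scan(self):
        # tracks with one inserted segment: the accepted arc must match a
        # brute-force maximum-statistic scan within one bin
        rng = np.random.default_rng(30)
        for _ in range(10):
            n = int(rng.integers(40, 121))
            a = int(rng.integers(5, n - 20))
            b = a + int(rng.integers(5, min(20, n - a - 4)))
            x = np.full(n, 1.0)
            x[a:b] += rng.choice([-0.8, 0.8])
            x += rng.normal(0, 0.1, n)
            i, j, _t = exhaustive_best_arc(x, 3)
            segs = CBSSegmenter().segment(x)
            bounds = {p for seg in segs for p in seg}
            assert any(abs(i - p) <= 1 for p in bounds)
            assert any(abs(j - p) <= 1 for p in bounds)


class TestPermutationP:
    def test_null_segment_has_large_p(self):
        rng = np.random.default_rng(31)
        x = rng.normal(1.0, 0.1, 80)
        # a segment whose mean happens to equal the track mean
        p = permutation_p((0, 80), x, n_perm=200, seed=1)
        assert p == 1.0
        p = permutation_p((10, 50), x, n_perm=500, seed=1)
        assert p >= 0.05

    def test_strong_segment_is_significant(self):
        # 10 superbins at copy 3 (ratio 1.5) in a diploid track, bin sd 0.2
        # on the copy scale (0.1 on the ratio scale)
        rng = np.random.default_rng(32)
        x = rng.normal(1.0, 0.1, 120)
        x[40:50] += 0.5
        p = permutation_p((40, 50), x, n_perm=2_000, seed=7)
        assert p < 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(33)
        x = rng.normal(1.0, 0.1, 60)
        x[10:20] += 0.3
        p1 = permutation_p((10, 20), x, n_perm=500, seed=42)
        p2 = permutation_p((10, 20), x, n_perm=500, seed=42)
        assert p1 == p2

    def test_errors(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            permutation_p((0, 20), x, n_perm=200, seed=0)
        with pytest.raises(ValueError):
            permutation_p((0, 5), x, n_perm=50, seed=0)


def seg(chrom="chr1", start=0, end=5_000_000, n_bins=10, mean_ratio=1.0,
        p=0.001):
    return {"chrom": chrom, "start": start, "end": end, "n_bins": n_bins,
            "mean_ratio": mean_ratio, "p_perm": p}


class TestClassifySegments:
    @pytest.mark.parametrize("mean_copy,p,label,detected", [
        (1.0, 0.001, "microdeletion", True),    # pure deletion
        (2.0, 0.5, "neutral", False),
        (2.7, 0.001, "microduplication", True),  # 0.7-mixing duplication
        (2.3, 0.001, "intermediate", True),      # 0.3-mixing duplication
        (1.7, 0.001, "intermediate", True),      # 0.3-mixing deletion
        (2.3, 0.5, "neutral", False),            # not significant
        (3.0, 0.5, "microduplication", False),   # labeled but not detected
        (2.1, 0.001, "neutral", False),          # significant but tiny effect
    ])
    def test_labels_and_detection(self, mean_copy, p, label, detected):
        calls = classify_segments([seg(mean_ratio=mean_copy / 2, p=p)])
        assert calls[0].label == label
        assert calls[0].detected is detected

    def test_inverted_thresholds_error(self):
        with pytest.raises(ValueError):
            classify_segments([seg()], del_thr=2.6, dup_thr=1.4)


class TestDecideImplantable:
    def chrom_calls(self, grid, abnormal=()):
        calls = []
        for c in grid.chroms:
            kind = dict(abnormal).get(c, "disomy")
            calls.append(ChromCall(c, 1.0, 0.0, kind))
        return calls

    def test_truth_table(self, toy_grid):
        cnv_det = CnvCall("chr1", 0, 5_000_000, 10, 1.0, 1e-4,
                          "microdeletion", True)
        cnv_lab = CnvCall("chr1", 0, 5_000_000, 10, 3.0, 0.9,
                          "microduplication", False)
        ok = self.chrom_calls(toy_grid)
        tri = self.chrom_calls(toy_grid, [("chr2", "trisomy")])
        assert decide_implantable(ok, [], expected_chroms=toy_grid.chroms)
        assert not decide_implantable(tri, [], expected_chroms=toy_grid.chroms)
        assert not decide_implantable(ok, [cnv_det],
                                      expected_chroms=toy_grid.chroms)
        # a labeled-but-undetected segment does not veto implantation
        assert decide_implantable(ok, [cnv_lab],
                                  expected_chroms=toy_grid.chroms)

    def test_missing_chromosome_error(self, toy_grid):
        calls = self.chrom_calls(toy_grid)[:-1]
        with pytest.raises(ValueError, match="chr3"):
            decide_implantable(calls, [], expected_chroms=toy_grid.chroms)


class TestArrayCGHComparator:
    def test_thresholds(self):
        out = arraycgh_like_call({"chr1": 0.58, "chr2": 0.0, "chr3": -1.0,
                                  "chr4": 0.3, "chr5": -0.29})
        assert out == {"chr1": "gain", "chr2": "neutral", "chr3": "loss",
                       "chr4": "gain", "chr5": "neutral"}


def test_unfitted_screen_raises(toy_grid):
    with pytest.raises(RuntimeError):
        s.EmbryoScreen(toy_grid).predict(
            s.CountProfile("x", np.ones(toy_grid.n_bins, dtype=np.int64),
                           n_total_reads=toy_grid.n_bins,
                           n_unique_mapped=toy_grid.n_bins))
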