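import numpy as np
import pytest

from scclone.genome import build_genome
from scclone.segment import (
    CNVEvent,
    Segment,
    call_integer_cn,
    cbs_segment,
    classify_scale,
    cn_from_log2,
    consolidate_cnvs,
    merge_segments,
    segment_profile,
)


def brute_force_changepoint(x: np.ndarray) -> int:
    """Independent oracle: exhaustive single-split t-like maximizer."""
    n = len(x)
    sd = x.std(ddof=1)
    best_t, best_i = -1.0, 0
    for i in range(1, n):
        a, b = x[:i], x[i:]
        t = abs(a.mean() - b.mean()) / (sd * np.sqrt(1 / i + 1 / (n - i)))
        if t > best_t:
            best_t, best_i = t, i
    return best_i


@pytest.fixture(scope="module")
def g200():
    """One 10 Mb chromosome = 200 bins."""
    return build_genome({"chr1": 10_000_000}, {"chr1": 4_000_000})


class TestCbs:
    def test_constant_profile_single_segment(self, g200):
        segs = cbs_segment(np.zeros(200), g200, seed=0)
        assert len(segs) == 1
        assert (segs[0].start_bin, segs[0].end_bin) == (0, 200)

    def test_noiseless_step_breaks_exactly(self, g200):
        x = np.zeros(200)
        x[100:] = 1.0
        segs = cbs_segment(x, g200, seed=0)
        assert [(s.start_bin, s.end_bin) for s in segs] == [(0, 100), (100, 200)]

    def test_noisy_step_matches_bruteforce_maximizer(self, g200):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 0.3, 200)
            x[100:] += 1.0
            oracle = brute_force_changepoint(x)
            segs = cbs_segment(x, g200, seed=seed)
            breaks = [s.start_bin for s in segs[1:]]
            if any(abs(b - oracle) <= 2 for b in breaks):
                hits += 1
        assert hits >= 19

    def test_interior_arc_yields_two_breakpoints(self, g200):
        x = np.zeros(200)
        x[80:120] = 1.5
        segs = cbs_segment(x, g200, seed=0)
        assert [(s.start_bin, s.end_bin) for s in segs] == [
            (0, 80), (80, 120), (120, 200)
        ]

    def test_masked_bins_are_absorbed(self, g200):
        x = np.zeros(200)
        x[100:] = 1.0
        x[50:55] = np.nan
        segs = cbs_segment(x, g200, seed=0)
        assert [s.start_bin for s in segs] == [0, 100]
        assert sum(s.n_bins for s in segs) == 195
        assert segs[-1].end_bin == 200

    def test_segments_tile_chromosome(self, g200):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, 200)
        x[60:] += 1.0
        segs = cbs_segment(x, g200, seed=7)
        assert segs[0].start_bin == 0
        assert segs[-1].end_bin == 200
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_bin == b.start_bin

    def test_warns_when_alpha_unresolvable(self, g200):
        with pytest.warns(UserWarning, match="unresolvable"):
            cbs_segment(np.zeros(200), g200, alpha=1e-5, n_permutations=10, seed=0)

    def test_multi_changepoint_recovery(self, g200):
        """K true changepoints of magnitude >= 1 recovered in >= 90% of seeds."""
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(0, 0.24, 200)
            x[50:100] += 1.0
            x[150:] -= 1.0
            segs = cbs_segment(x, g200, seed=seed)
            if len(segs) == 4:
                ok += 1
        assert ok >= 0.9 * n_seeds


class TestCnCalling:
    @pytest.mark.parametrize(
        "mean_log2,expected",
        [(0.0, 2), (-1.0, 1), (0.585, 3), (1.0, 4), (-8.0, 0), (3.0, 8)],
    )
    def test_rounding_rule(self, mean_log2, expected):
        assert cn_from_log2(mean_log2) == expected

    @pytest.mark.parametrize(
        "mean_log2,expected",
        [(0.0, 2), (0.585, 2), (-0.9, 2), (-1.0, 1), (1.0, 4)],
    )
    def test_literal_mode_flags_only_at_unit_thresholds(self, mean_log2, expected):
        assert cn_from_log2(mean_log2, mode="literal") == expected

    def test_call_integer_cn_sets_field(self, g200):
        segs = cbs_segment(np.zeros(200), g200, seed=0)
        call_integer_cn(segs)
        assert all(s.cn == 2 for s in segs)


def _seg(chrom, a, b, mean, cn=None, g=None):
    return Segment(
        chrom=chrom, start_bin=a, end_bin=b,
        start_bp=a * 50_000, end_bp=b * 50_000,
        mean_log2=mean, n_bins=b - a, cn=cn,
    )


class TestMerge:
    def test_same_cn_neighbours_merge(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0.02, 0.1, 50), rng.normal(-0.01, 0.1, 50)])
        segs = [_seg("chr1", 0, 50, 0.02), _seg("chr1", 50, 100, -0.01)]
        out = merge_segments(segs, vals)
        assert len(out) == 1
        assert out[0].cn == 2
        assert out[0].n_bins == 100

    def test_distinct_cn_neighbours_stay(self):
        vals = np.concatenate([np.full(50, -1.0), np.full(50, 0.585)])
        segs = [_seg("chr1", 0, 50, -1.0), _seg("chr1", 50, 100, 0.585)]
        out = merge_segments(segs, vals)
        assert [s.cn for s in out] == [1, 3]

    def test_chain_merge_direction_independent(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.05, 90)
        segs = [
            _seg("chr1", 0, 30, float(vals[:30].mean())),
            _seg("chr1", 30, 60, float(vals[30:60].mean())),
            _seg("chr1", 60, 90, float(vals[60:].mean())),
        ]
        fwd = merge_segments(segs, vals)
        rev = merge_segments(list(reversed(segs)), vals)
        assert [(s.start_bin, s.end_bin, s.cn) for s in fwd] == [
            (s.start_bin, s.end_bin, s.cn) for s in rev
        ]
        assert len(fwd) == 1

    def test_different_chromosomes_never_merge(self):
        vals = np.zeros(100)
        segs = [_seg("chr1", 0, 50, 0.0), _seg("chr2", 50, 100, 0.0)]
        assert len(merge_segments(segs, vals)) == 2


class TestConsolidate:
    @pytest.fixture
    def grid(self):
        return build_genome({"chr1": 10_000_000}, {"chr1": 4_000_000})

    def _cells(self, coords_cn, grid):
        """coords_cn: dict cell -> (start, end, cn)."""
        out = {}
        for cell, (a, b, cn) in coords_cn.items():
            segs = []
            if a > 0:
                segs.append(_seg("chr1", 0, a, 0.0, 2))
            segs.append(_seg("chr1", a, b, -1.0 if cn < 2 else 1.0, cn))
            if b < 200:
                segs.append(_seg("chr1", b, 200, 0.0, 2))
            out[cell] = segs
        return out

    def test_three_identical_cells_one_event(self, grid):
        cells = self._cells({f"c{i}": (50, 100, 1) for i in range(3)}, grid)
        events = consolidate_cnvs(cells, grid)
        assert len(events) == 1
        assert events[0].n_cells == 3
        assert (events[0].start_bin, events[0].end_bin) == (50, 100)

    def test_two_cells_below_threshold(self, grid):
        cells = self._cells({f"c{i}": (50, 100, 1) for i in range(2)}, grid)
        assert consolidate_cnvs(cells, grid) == []

    def test_jittered_boundaries_grouped_at_median(self, grid):
        cells = self._cells(
            {"c0": (49, 100, 1), "c1": (50, 101, 1), "c2": (51, 99, 1)}, grid
        )
        events = consolidate_cnvs(cells, grid)
        assert len(events) == 1
        assert (events[0].start_bin, events[0].end_bin) == (50, 100)

    def test_gain_and_loss_not_grouped(self, grid):
        cells = self._cells(
            {"c0": (50, 100, 1), "c1": (50, 100, 1), "c2": (50, 100, 1),
             "c3": (50, 100, 3), "c4": (50, 100, 3), "c5": (50, 100, 3)},
            grid,
        )
        events = consolidate_cnvs(cells, grid)
        assert sorted(e.direction for e in events) == ["gain", "loss"]

    def test_cell_order_invariance(self, grid):
        cells = self._cells(
            {"c0": (49, 100, 1), "c1": (50, 101, 1), "c2": (51, 99, 1),
             "c3": (120, 180, 3), "c4": (121, 181, 3), "c5": (119, 179, 3)},
            grid,
        )
        ev1 = consolidate_cnvs(cells, grid)
        shuffled = dict(reversed(list(cells.items())))
        ev2 = consolidate_cnvs(shuffled, grid)
        assert [e.key() for e in ev1] == [e.key() for e in ev2]


class TestClassifyScale:
    @pytest.fixture
    def grid(self):
        # chr1: 40 Mb (800 bins), arms 16/24 Mb
        return build_genome({"chr1": 40_000_000}, {"chr1": 16_000_000})

    def _event(self, a, b):
        return CNVEvent(
            chrom="chr1", start_bin=a, end_bin=b,
            start_bp=a * 50_000, end_bp=b * 50_000,
            direction="loss", cn=1, cells=["c0", "c1", "c2"],
        )

    def test_95pct_coverage_is_whole_chromosome(self, grid):
        assert classify_scale(self._event(0, 760), grid) == "whole_chromosome"

    def test_full_arm_is_whole_arm(self, grid):
        assert classify_scale(self._event(0, 320), grid) == "whole_arm"
        assert classify_scale(self._event(330, 800), grid) == "whole_arm"

    def test_20mb_interior_is_subchromosomal(self, grid):
        assert classify_scale(self._event(100, 500), grid) == "subchromosomal"

    def test_2p5mb_is_focal(self, grid):
        assert classify_scale(self._event(100, 150), grid) == "focal"

    def test_6p5mb_is_focal(self, grid):
        assert classify_scale(self._event(400, 530), grid) == "focal"


def test_end_to_end_focal_amplification(grid):
    """A 50-bin CN4 amplification in >= 3 cells comes out as a focal gain."""
    from scclone.qc import build_normal_panel, log2_ratios
    from scclone.simulate import (
        CloneSpec, SimulationParams, TrueEvent, simulate_cells, validate_clone_truth,
    )

    # 2.5 Mb CN4 amplification on chr1 q arm (bins 200-250 of chr1)
    truth = validate_clone_truth(
        [CloneSpec("A", None,
                   events=[TrueEvent("chr1", 10_000_000, 12_500_000, 4)],
                   fractions={"r1": 1.0, "r2": 1.0})],
        grid,
    )
    params = SimulationParams(cells_per_region=3, n_reference_normals=20,
                              outlier_fraction=0.0, seed=21)
    counts, meta, _, _ = simulate_cells(grid, truth, params)
    ref = list(meta.loc[meta.origin == "normal_reference", "cell_id"])
    samp = list(meta.loc[meta.origin != "normal_reference", "cell_id"])
    panel = build_normal_panel(counts[ref])
    cell_segments = {
        c: segment_profile(log2_ratios(counts[c], panel, c).values, grid, seed=i)
        for i, c in enumerate(samp)
    }
    events = consolidate_cnvs(cell_segments, grid)
    gains = [e for e in events if e.direction == "gain"]
    assert len(gains) == 1
    ev = gains[0]
    assert ev.scale == "focal"
    assert ev.n_cells >= 3
    assert abs(ev.start_bin - 200) <= 2 and abs(ev.end_bin - 250) <= 2
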