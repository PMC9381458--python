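"""Circular binary segmentation, integer copy-number calls and recurrent
CNV consolidation.

Per-cell log2-ratio profiles are segmented chromosome by chromosome with a
recursive circular binary segmentation (CBS): the arc (i, j] maximizing a
standardized mean-difference statistic between inside and outside is
accepted as a split when its within-chromosome permutation p-value falls
below ``alpha`` (default 1e-5), and the procedure recurses on the
resulting pieces.  Adjacent segments with equal integer copy number, or
whose bin-level values are not significantly different (Welch test,
p >= 0.01), are merged to a fixpoint.  Integer copy numbers derive from
the segment mean m as round(2 * 2**m) clipped to [0, 8]; a literal
single-copy-threshold mode (aberrant only at |m| >= 1) is provided as an
alternative.  Aberrant segments recurring with consistent coordinates in
at least three cells are consolidated into CNV events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import BinGrid

MAX_CN = 8
MIN_SUPPORTING_CELLS = 3


@dataclass
class Segment:
    chrom: str
    start_bin: int  # global bin index, half-open
    end_bin: int
    start_bp: int
    end_bp: int
    mean_log2: float
    n_bins: int  # unmasked bins contributing to the mean
    cn: int | None = None

    @property
    def is_aberrant(self) -> bool:
        return self.cn is not None and self.cn != 2


@dataclass
class CNVEvent:
    chrom: str
    start_bin: int
    end_bin: int
    start_bp: int
    end_bp: int
    direction: str  # "gain" | "loss"
    cn: int
    cells: list[str]
    region_counts: dict[str, int] = field(default_factory=dict)
    scale: str | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def key(self) -> tuple:
        return (self.chrom, self.start_bin, self.end_bin, self.direction)


# ---------------------------------------------------------------------------
# CBS core
# ---------------------------------------------------------------------------


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Max standardized mean-difference statistic over all arcs of ``x``.

    Returns (T, i, j) for the best arc (i, j] (0 <= i < j <= n, not the
    full circle).  The statistic is |mean_in - mean_out| scaled by the
    piece SD and the two-sample factor sqrt(1/k + 1/(n-k)).
    """
    n = x.size
    sd = x.std(ddof=1)
    if sd <= 0 or n < 2:
        return 0.0, 0, n
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    best_t, best_i, best_j = 0.0, 0, n
    for k in range(1, n):
        sums = S[k:] - S[:-k]  # windows (i, i+k], i = 0..n-k
        t = np.abs(sums / k - (tot - sums) / (n - k)) / (
            sd * np.sqrt(1.0 / k + 1.0 / (n - k))
        )
        i = int(np.argmax(t))
        if t[i] > best_t:
            best_t, best_i, best_j = float(t[i]), i, i + k
    return best_t, best_i, best_j


def _perm_max_stats(
    x: np.ndarray,
    rng: np.random.Generator,
    batch: int,
    stop_stat: float | None = None,
    stop_count: int = 0,
) -> np.ndarray:
    """Max arc statistic for ``batch`` within-piece permutations of ``x``.

    When ``stop_stat`` is given, the scan over arc lengths aborts once more
    than ``stop_count`` permutations already exceed it (their maxima are
    then lower bounds, which is all the sequential test needs).
    """
    n = x.size
    sd = x.std(ddof=1)
    perms = rng.permuted(np.tile(x.astype(np.float32), (batch, 1)), axis=1)
    S = np.concatenate(
        [np.zeros((batch, 1), dtype=np.float64), np.cumsum(perms, axis=1, dtype=np.float64)],
        axis=1,
    )
    tot = S[:, -1:]
    best = np.zeros(batch)
    for k in range(1, n):
        sums = S[:, k:] - S[:, :-k]
        scale = sd * np.sqrt(1.0 / k + 1.0 / (n - k))
        t = np.abs(sums / k - (tot - sums) / (n - k)) / scale
        np.maximum(best, t.max(axis=1), out=best)
        if stop_stat is not None and k % 32 == 0:
            if int(np.sum(best >= stop_stat)) > stop_count:
                break
    return best


def _split_accepted(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> bool:
    """Sequential permutation test of the best arc.

    The split is accepted when the permutation estimate p = exceed/n stays
    below ``alpha``.  Permutations run in growing batches and stop as soon
    as the exceedance count already forces p >= alpha, which makes
    null splits cheap and spends full permutations only on real ones.
    """
    allowed = int(np.floor(alpha * n_permutations))  # max tolerable exceedances
    done = 0
    exceed = 0
    batch = 16
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        maxima = _perm_max_stats(
            x, rng, b, stop_stat=t_obs - 1e-12, stop_count=allowed - exceed
        )
        exceed += int(np.sum(maxima >= t_obs - 1e-12))
        done += b
        if exceed > allowed:
            return False
        batch = min(batch * 4, 512)
    return exceed / n_permutations < alpha


def _segment_piece(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
    out: list[tuple[int, int]],
    min_split: int = 4,
) -> None:
    n = x.size
    if n >= min_split:
        t_obs, i, j = _max_arc_stat(x)
        if t_obs > 0 and _split_accepted(x, t_obs, alpha, n_permutations, rng):
            cuts = sorted({c for c in (i, j) if 0 < c < n})
            if cuts:
                edges = [0] + cuts + [n]
                for a, b in zip(edges[:-1], edges[1:]):
                    _segment_piece(
                        x[a:b], offset + a, alpha, n_permutations, rng, out, min_split
                    )
                return
    out.append((offset, offset + n))


def cbs_segment(
    values: np.ndarray,
    grid: BinGrid,
    alpha: float = 1e-5,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """Segment a per-bin log2-ratio profile chromosome by chromosome.

    ``values`` is aligned with ``grid.bins``; NaN entries (masked bins) are
    ignored when computing statistics and segment means but remain covered
    by the surrounding segment, so the output tiles every chromosome.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 1.0 / alpha:
        warnings.warn(
            f"alpha={alpha:g} is unresolvable with {n_permutations} permutations "
            f"(minimum attainable p is 1/{n_permutations}); splits are accepted "
            "when no permutation reaches the observed statistic",
            stacklevel=2,
        )
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    starts_bp = grid.bins["start"].to_numpy()
    ends_bp = grid.bins["end"].to_numpy()
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        chrom_vals = values[sl]
        good = np.nonzero(~np.isnan(chrom_vals))[0]
        if good.size < 2:
            if good.size == 0:
                continue
            pieces = [(0, 1)]
        else:
            pieces = []
            _segment_piece(
                chrom_vals[good], 0, alpha, n_permutations, rng, pieces
            )
            pieces.sort()
        n_chrom = sl.stop - sl.start
        for pi, (a, b) in enumerate(pieces):
            # map unmasked-position piece back to global bin indices; a
            # segment stretches to just before the next segment's first bin
            first = int(good[a])
            last_excl = int(good[b - 1]) + 1 if pi == len(pieces) - 1 else int(good[b])
            if pi == 0:
                first = 0
            if pi == len(pieces) - 1:
                last_excl = n_chrom
            seg_vals = chrom_vals[good[a:b]]
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=sl.start + first,
                    end_bin=sl.start + last_excl,
                    start_bp=int(starts_bp[sl.start + first]),
                    end_bp=int(ends_bp[sl.start + last_excl - 1]),
                    mean_log2=float(np.mean(seg_vals)),
                    n_bins=int(b - a),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# CN calling and segment merging
# ---------------------------------------------------------------------------


def cn_from_log2(mean_log2: float, mode: str = "rounding") -> int:
    """Integer copy number from a segment mean log2 ratio.

    ``rounding``: CN = round(2 * 2**m) clipped to [0, 8], so a single-copy
    gain (m ~ 0.585) and loss (m ~ -1) both land on the correct integer.
    ``literal``: a segment is aberrant only when |m| >= 1 (the single-copy
    thresholds as printed), otherwise CN = 2; note this convention cannot
    represent a single-copy gain, whose expected ratio is log2(3/2) = 0.585.
    """
    cn = int(np.clip(np.rint(2.0 * 2.0 ** mean_log2), 0, MAX_CN))
    if mode == "rounding":
        return cn
    if mode == "literal":
        return cn if abs(mean_log2) >= 1.0 else 2
    raise ValueError(f"unknown CN-calling mode {mode!r}")


def call_integer_cn(segments: list[Segment], mode: str = "rounding") -> list[Segment]:
    """Assign integer copy numbers to segments in place (and return them)."""
    for seg in segments:
        seg.cn = cn_from_log2(seg.mean_log2, mode=mode)
    return segments


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def merge_segments(
    segments: list[Segment],
    values: np.ndarray,
    merge_p: float = 0.01,
    cn_mode: str = "rounding",
) -> list[Segment]:
    """Merge adjacent same-chromosome segments to a fixpoint.

    Two neighbours merge when their integer copy numbers are equal, or when
    a Welch two-sample test on their bin-level log2 values is
    non-significant (p >= ``merge_p``).  Merged means and copy numbers are
    re-computed from the underlying bins; passes repeat until stable, so
    the result is independent of scan direction.
    """
    values = np.asarray(values, dtype=float)
    segs = [Segment(**vars(s)) for s in sorted(segments, key=lambda s: s.start_bin)]
    if any(s.cn is None for s in segs):
        call_integer_cn(segs, mode=cn_mode)

    def bin_vals(s: Segment) -> np.ndarray:
        return values[s.start_bin : s.end_bin]

    changed = True
    while changed:
        changed = False
        out: list[Segment] = []
        for seg in segs:
            if out and out[-1].chrom == seg.chrom:
                prev = out[-1]
                p = _welch_p(bin_vals(prev), bin_vals(seg))
                if prev.cn == seg.cn or (not np.isnan(p) and p >= merge_p):
                    merged_vals = values[prev.start_bin : seg.end_bin]
                    merged_vals = merged_vals[~np.isnan(merged_vals)]
                    prev.end_bin = seg.end_bin
                    prev.end_bp = seg.end_bp
                    prev.mean_log2 = float(merged_vals.mean())
                    prev.n_bins = int(merged_vals.size)
                    prev.cn = cn_from_log2(prev.mean_log2, mode=cn_mode)
                    changed = True
                    continue
            out.append(seg)
        segs = out
    return segs


def segment_profile(
    values: np.ndarray,
    grid: BinGrid,
    alpha: float = 1e-5,
    n_permutations: int = 1000,
    seed: int = 0,
    cn_mode: str = "rounding",
    merge_p: float = 0.01,
) -> list[Segment]:
    """CBS + CN calling + merging for one cell's log2-ratio profile."""
    segs = cbs_segment(values, grid, alpha=alpha, n_permutations=n_permutations, seed=seed)
    call_integer_cn(segs, mode=cn_mode)
    return merge_segments(segs, values, merge_p=merge_p, cn_mode=cn_mode)


# ---------------------------------------------------------------------------
# Cross-cell CNV consolidation
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _coords_match(
    a: tuple[int, int], b: tuple[int, int], tol_bins: int, min_overlap: float
) -> bool:
    (s1, e1), (s2, e2) = a, b
    inter = min(e1, e2) - max(s1, s2)
    if inter > 0:
        ro = min(inter / (e1 - s1), inter / (e2 - s2))
        if ro >= min_overlap:
            return True
    return abs(s1 - s2) <= tol_bins and abs(e1 - e2) <= tol_bins


def consolidate_cnvs(
    cell_segments: dict[str, list[Segment]],
    grid: BinGrid,
    tol_bins: int = 2,
    min_overlap: float = 0.8,
    min_cells: int = MIN_SUPPORTING_CELLS,
    cell_regions: dict[str, str] | None = None,
) -> list[CNVEvent]:
    """Group recurrent aberrant segments into CNV events.

    Aberrant segments from different cells on the same chromosome and in
    the same direction are grouped by transitive closure of a coordinate
    match (reciprocal overlap >= ``min_overlap``, or both boundaries within
    ``tol_bins``).  Groups supported by >= ``min_cells`` distinct cells
    become events with median boundaries; smaller groups are discarded.
    The output is invariant to the order cells are supplied in.
    """
    records = []  # (chrom, direction, start_bin, end_bin, cn, cell)
    for cell in sorted(cell_segments):
        for seg in cell_segments[cell]:
            if seg.is_aberrant:
                direction = "gain" if seg.cn > 2 else "loss"
                records.append(
                    (seg.chrom, direction, seg.start_bin, seg.end_bin, seg.cn, cell)
                )
    events: list[CNVEvent] = []
    starts_bp = grid.bins["start"].to_numpy()
    ends_bp = grid.bins["end"].to_numpy()
    groups_keys = sorted({(r[0], r[1]) for r in records})
    for chrom, direction in groups_keys:
        recs = [r for r in records if r[0] == chrom and r[1] == direction]
        uf = _UnionFind(len(recs))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if _coords_match(
                    (recs[i][2], recs[i][3]),
                    (recs[j][2], recs[j][3]),
                    tol_bins,
                    min_overlap,
                ):
                    uf.union(i, j)
        clusters: dict[int, list[int]] = {}
        for i in range(len(recs)):
            clusters.setdefault(uf.find(i), []).append(i)
        for members in clusters.values():
            cells = sorted({recs[i][5] for i in members})
            if len(cells) < min_cells:
                continue
            s = int(np.median([recs[i][2] for i in members]))
            e = int(np.median([recs[i][3] for i in members]))
            cn = int(np.median([recs[i][4] for i in members]))
            region_counts: dict[str, int] = {}
            if cell_regions is not None:
                for c in cells:
                    r = cell_regions.get(c)
                    if r is not None:
                        region_counts[r] = region_counts.get(r, 0) + 1
            events.append(
                CNVEvent(
                    chrom=chrom,
                    start_bin=s,
                    end_bin=e,
                    start_bp=int(starts_bp[s]),
                    end_bp=int(ends_bp[e - 1]),
                    direction=direction,
                    cn=cn,
                    cells=cells,
                    region_counts=region_counts,
                )
            )
    events.sort(key=lambda ev: (ev.chrom, ev.start_bin, ev.end_bin, ev.direction))
    for ev in events:
        ev.scale = classify_scale(ev, grid)
    return events


def classify_scale(
    event: CNVEvent,
    grid: BinGrid,
    arm_fraction: float = 0.9,
    focal_max_bp: int = 15_000_000,
) -> str:
    """Scale label for an event: whole-chromosome / whole-arm / subchromosomal / focal.

    Whole-chromosome when covering >= 90% of the chromosome's bins, else
    whole-arm when covering >= 90% of one arm, else subchromosomal when
    longer than 15 Mb, else focal.
    """
    sl = grid.chrom_slice(event.chrom)
    n_chrom = sl.stop - sl.start
    n_event = event.end_bin - event.start_bin
    if n_event / n_chrom >= arm_fraction:
        return "whole_chromosome"
    for arm in ("p", "q"):
        mask = grid.arm_mask(event.chrom, arm)
        n_arm = int(mask.sum())
        if n_arm == 0:
            continue
        covered = int(mask[event.start_bin : event.end_bin].sum())
        if covered / n_arm >= arm_fraction:
            return "whole_arm"
    if event.length_bp > focal_max_bp:
        return "subchromosomal"
    return "focal"
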