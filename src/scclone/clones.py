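"""Clonal substructure inference from per-cell segment profiles.

Cells are embedded in a common feature space by taking the union of all
segment breakpoints and evaluating every cell's integer copy number on the
unified segments.  Euclidean distances weighted by segment bin counts
(equivalent to per-bin distances, at a fraction of the cost) feed Ward
hierarchical clustering; the number of clusters is chosen by consensus of
the elbow, silhouette and gap-statistic criteria, and cross-checked with
k-means on a 2-component PCA projection.  Clusters whose consensus profile
is diploid everywhere are flagged as normal cells, giving the tumour
purity; remaining clusters are the tumour clones, lettered by size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .segment import Segment


class GridMismatchError(ValueError):
    pass


class SensitivityUndefinedError(ValueError):
    pass


@dataclass
class SegmentMatrix:
    """Cells x unified-segments integer copy-number matrix."""

    matrix: pd.DataFrame  # rows = cells, columns = segment index
    segments: pd.DataFrame  # chrom, start_bin, end_bin, n_bins
    weights: np.ndarray  # per-segment bin counts

    @property
    def cells(self) -> list[str]:
        return list(self.matrix.index)

    def weighted(self) -> np.ndarray:
        """Feature matrix scaled so Euclidean distance = per-bin distance."""
        return self.matrix.to_numpy(dtype=float) * np.sqrt(self.weights)


@dataclass
class Clone:
    clone_id: str
    cells: list[str]
    consensus: np.ndarray  # per unified segment, majority CN
    is_normal: bool
    region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.cells)


def build_segment_matrix(cell_segments: dict[str, list[Segment]]) -> SegmentMatrix:
    """Unify breakpoints across cells and evaluate each cell on them.

    Every cell's row reproduces its own segment profile bin-for-bin when
    expanded, because unified segments never straddle any cell's
    breakpoints.
    """
    if not cell_segments:
        raise ValueError("no cells supplied")
    # collect breakpoints per chromosome
    chrom_bounds: dict[str, set[int]] = {}
    chrom_extent: dict[str, tuple[int, int]] = {}
    for segs in cell_segments.values():
        for s in segs:
            b = chrom_bounds.setdefault(s.chrom, set())
            b.add(s.start_bin)
            b.add(s.end_bin)
            lo, hi = chrom_extent.get(s.chrom, (s.start_bin, s.end_bin))
            chrom_extent[s.chrom] = (min(lo, s.start_bin), max(hi, s.end_bin))
    for chrom, (lo, hi) in chrom_extent.items():
        if (lo, hi) != (min(chrom_bounds[chrom]), max(chrom_bounds[chrom])):
            raise GridMismatchError(f"inconsistent extent on {chrom}")

    seg_rows = []
    for chrom in sorted(chrom_bounds, key=_chrom_sort_key):
        edges = sorted(chrom_bounds[chrom])
        for a, b in zip(edges[:-1], edges[1:]):
            seg_rows.append({"chrom": chrom, "start_bin": a, "end_bin": b, "n_bins": b - a})
    segments = pd.DataFrame(seg_rows)

    cells = sorted(cell_segments)
    mat = np.full((len(cells), len(segments)), 2, dtype=np.int16)
    seg_lookup = {
        chrom: [
            (row.start_bin, row.end_bin, i)
            for i, row in segments.iterrows()
            if row.chrom == chrom
        ]
        for chrom in chrom_bounds
    }
    for ci, cell in enumerate(cells):
        for s in cell_segments[cell]:
            if s.cn is None:
                raise ValueError(f"cell {cell} has uncalled segment on {s.chrom}")
            for a, b, i in seg_lookup[s.chrom]:
                if a >= s.start_bin and b <= s.end_bin:
                    mat[ci, i] = s.cn
    matrix = pd.DataFrame(mat, index=cells)
    return SegmentMatrix(
        matrix=matrix,
        segments=segments,
        weights=segments["n_bins"].to_numpy(dtype=float),
    )


def _chrom_sort_key(chrom: str):
    tail = chrom.removeprefix("chr")
    return (0, int(tail)) if tail.isdigit() else (1, tail)


def cluster_cells(matrix: SegmentMatrix, k: int) -> np.ndarray:
    """Ward hierarchical clustering cut at ``k`` clusters (deterministic).

    Returns integer labels (1..k) in the cell order of the matrix.
    """
    n = len(matrix.cells)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == 1:
        return np.ones(n, dtype=int)
    Z = linkage(matrix.weighted(), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def choose_k(
    matrix: SegmentMatrix,
    k_max: int = 6,
    gap_b: int = 50,
    seed: int = 0,
) -> tuple[int, dict[str, int | None]]:
    """Consensus optimal cluster number from elbow, silhouette and gap.

    * elbow: argmax of the second difference of within-cluster sum of
      squares over k = 1..k_max (defined for k = 2..k_max-1);
    * silhouette: argmax of the mean silhouette over k = 2..k_max
      (undefined at k = 1, so this method abstains there);
    * gap statistic: smallest k with Gap(k) >= Gap(k+1) - s(k+1), with a
      uniform-box reference (B = ``gap_b``, seeded) — the only criterion
      defined at k = 1.

    Majority vote decides; ties break toward the gap statistic's k.
    Returns ``(k, votes)``.
    """
    X = matrix.weighted()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 cells to choose k")
    k_max = min(k_max, n - 1)
    ks = list(range(1, k_max + 1))
    labels_k = {k: cluster_cells(matrix, k) for k in ks}
    wss = np.array([_wss(X, labels_k[k]) for k in ks])

    votes: dict[str, int | None] = {}

    # elbow
    if len(ks) >= 3:
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]  # at k = 2..k_max-1
        votes["elbow"] = int(ks[1 + int(np.argmax(second_diff))])
    else:
        votes["elbow"] = None

    # silhouette
    sil_scores = {}
    for k in ks:
        if k == 1:
            continue
        labs = labels_k[k]
        if len(np.unique(labs)) < 2:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            try:
                sil_scores[k] = silhouette_score(X, labs)
            except ValueError:
                continue
    votes["silhouette"] = max(sil_scores, key=sil_scores.get) if sil_scores else None

    # gap statistic (uniform box reference)
    rng = np.random.default_rng(seed)
    eps = 1e-12
    log_w = np.log(np.maximum(wss, eps))
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log_w = np.empty((gap_b, len(ks)))
    for b in range(gap_b):
        R = rng.uniform(lo, hi, size=X.shape)
        Zr = linkage(R, method="ward") if n > 1 else None
        for ki, k in enumerate(ks):
            labs = (
                np.ones(n, dtype=int)
                if k == 1
                else fcluster(Zr, t=k, criterion="maxclust")
            )
            ref_log_w[b, ki] = np.log(np.maximum(_wss(R, labs), eps))
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0) * np.sqrt(1.0 + 1.0 / gap_b)
    gap_k = ks[-1]
    for ki in range(len(ks) - 1):
        if gap[ki] >= gap[ki + 1] - s[ki + 1]:
            gap_k = ks[ki]
            break
    votes["gap"] = int(gap_k)

    counts: dict[int, int] = {}
    for v in votes.values():
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == best)
    k_star = votes["gap"] if votes["gap"] in winners else winners[0]
    return int(k_star), votes


def pca_kmeans_check(
    matrix: SegmentMatrix, k: int, seed: int = 0, flag_below: float = 0.7
) -> tuple[float, bool]:
    """Concordance (ARI) of Ward labels with k-means on a 2-PC projection.

    Returns ``(ari, flagged)``; ARI is 1 by convention at k = 1.
    """
    if k == 1:
        return 1.0, False
    hier = cluster_cells(matrix, k)
    X = matrix.weighted()
    n_comp = min(2, X.shape[1], X.shape[0])
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(proj)
    ari = float(adjusted_rand_score(hier, km))
    return ari, ari < flag_below


def enforce_min_clone_size(
    labels: np.ndarray, matrix: SegmentMatrix, min_size: int = 3
) -> np.ndarray:
    """Merge under-sized aberrant clusters into their nearest cluster.

    A copy-number pattern needs at least ``min_size`` independent cells to
    count as reproducible, so clusters of aberrant cells below that size
    are artefacts of segmentation noise rather than detectable clones;
    each is absorbed into the cluster with the nearest (bin-weighted)
    centroid.  All-diploid clusters are exempt: normal cells are defined
    by the absence of events, not by a recurrent pattern.
    """
    labels = np.asarray(labels).copy()
    X = matrix.weighted()
    mat = matrix.matrix.to_numpy()
    while True:
        labs, counts = np.unique(labels, return_counts=True)
        if len(labs) == 1:
            break
        small = [
            (c, l)
            for l, c in zip(labs, counts)
            if c < min_size and (mat[labels == l] != 2).any()
        ]
        if not small:
            break
        _, lab = min(small)
        centroid = X[labels == lab].mean(axis=0)
        others = [l for l in labs if l != lab]
        dists = [
            float(((X[labels == l].mean(axis=0) - centroid) ** 2).sum())
            for l in others
        ]
        labels[labels == lab] = others[int(np.argmin(dists))]
    return labels


def define_clones(
    labels: np.ndarray,
    matrix: SegmentMatrix,
    cell_regions: dict[str, str] | None = None,
) -> tuple[list[Clone], float]:
    """Consensus profiles, normal-cell flag, clone letters and purity.

    Per-segment consensus is the majority CN among member cells, with ties
    resolved toward CN 2 when diploid is among the tied values (erring
    toward calling cells normal).  A cluster is normal iff its consensus is
    CN 2 on every segment.  Purity is the fraction of cells in non-normal
    clusters.  Tumour clones are lettered A, B, C... by descending size.
    """
    cells = matrix.cells
    mat = matrix.matrix.to_numpy()
    clones: list[Clone] = []
    for lab in np.unique(labels):
        members = [c for c, l in zip(cells, labels) if l == lab]
        sub = mat[labels == lab]
        consensus = np.empty(sub.shape[1], dtype=np.int16)
        for j in range(sub.shape[1]):
            vals, counts = np.unique(sub[:, j], return_counts=True)
            tied = vals[counts == counts.max()]
            consensus[j] = 2 if 2 in tied else int(tied[0])
        region_counts: dict[str, int] = {}
        if cell_regions:
            for c in members:
                r = cell_regions.get(c)
                if r is not None:
                    region_counts[r] = region_counts.get(r, 0) + 1
        clones.append(
            Clone(
                clone_id="",
                cells=members,
                consensus=consensus,
                is_normal=bool((consensus == 2).all()),
                region_counts=region_counts,
            )
        )
    tumour = sorted(
        (c for c in clones if not c.is_normal), key=lambda c: (-c.size, c.cells[0])
    )
    for i, c in enumerate(tumour):
        c.clone_id = chr(ord("A") + i)
    normals = [c for c in clones if c.is_normal]
    for i, c in enumerate(normals):
        c.clone_id = "N" if len(normals) == 1 else f"N{i + 1}"
    purity = sum(c.size for c in tumour) / len(cells) if cells else float("nan")
    ordered = tumour + normals
    return ordered, purity


def detection_sensitivity(n_cells: int, min_cells: int = 3) -> float:
    """Minimum detectable clone fraction (percent) at the m-cell rule.

    With ``min_cells`` independent cells required to call a reproducible
    copy-number pattern, a clone is expected to be detectable when its
    fraction exceeds min_cells / n_cells.
    """
    if n_cells < min_cells:
        raise SensitivityUndefinedError(
            f"sensitivity undefined for {n_cells} cells (< {min_cells})"
        )
    return 100.0 * min_cells / n_cells


def substructure_category(n_tumour_clones: int) -> str:
    """Taxonomy of clonal substructure by tumour clone count: 1 / 2 / >=3."""
    if n_tumour_clones <= 0:
        raise ValueError("tumour must have at least one clone")
    if n_tumour_clones == 1:
        return "none"
    if n_tumour_clones == 2:
        return "moderate"
    return "extensive"
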