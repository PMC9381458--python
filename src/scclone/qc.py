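"""Per-cell quality control and panel-of-normals log2-ratio normalization.

Cells are screened on two criteria computed once on the full cohort:

* a bin-count filter excluding cells whose mean bin count lies more than
  two (sample) standard deviations from the cohort mean; and
* a derivative-MAD noise score — the median absolute deviation of
  consecutive-bin differences of the depth-normalized profile — with a
  data-driven default cutoff (cohort median MAD + 2 x MAD-of-MADs).

Passing cells are normalized against a reference panel built from diploid
normal cells (per-bin median of depth-normalized counts) and expressed as
per-bin log2 ratios.  Bins with zero panel coverage are masked and
propagate as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.5


class InsufficientReferenceError(ValueError):
    """Fewer than two normal cells available for the panel."""


class GridMismatchError(ValueError):
    """Counts and panel refer to different bin grids."""


@dataclass
class CellQCRecord:
    cell_id: str
    total_reads: int
    mean_bin_count: float
    mad: float
    sd_fail: bool
    mad_fail: bool
    zero_coverage: bool

    @property
    def passed(self) -> bool:
        return not (self.sd_fail or self.mad_fail or self.zero_coverage)


@dataclass
class NormalPanel:
    """Per-bin copy-number reference from diploid cells."""

    reference: np.ndarray  # per-bin median of depth-normalized counts
    mask: np.ndarray  # True where the bin is unusable (zero reference)
    n_cells: int


@dataclass
class LogRatioProfile:
    cell_id: str
    log2: np.ndarray  # NaN on masked bins
    mask: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.log2


def _depth_normalize(col: np.ndarray) -> np.ndarray:
    col = col.astype(float)
    m = col.mean()
    if m <= 0:
        return np.zeros_like(col)
    return col / m


def derivative_mad(normalized: np.ndarray) -> float:
    """MAD of consecutive-bin differences: a robust per-cell noise score."""
    d = np.diff(np.asarray(normalized, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))))


@dataclass
class CohortQCStats:
    """Frozen cohort statistics driving the per-cell filters."""

    mean_bin_count: float
    sd_bin_count: float
    mad_threshold: float


def cohort_qc_stats(
    counts: pd.DataFrame, mad_threshold: float | None = None
) -> CohortQCStats:
    """Single-pass cohort statistics: mean/SD of mean bin counts (sample
    SD, ddof=1) and the MAD cutoff (default: median MAD + 2 x MAD-of-MADs)."""
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 cells for cohort SD statistics")
    mat = counts.to_numpy(dtype=float)
    mean_bin = mat.mean(axis=0)
    mads = np.array(
        [derivative_mad(_depth_normalize(mat[:, j])) for j in range(mat.shape[1])]
    )
    if mad_threshold is None:
        med = np.median(mads)
        mad_of_mads = np.median(np.abs(mads - med))
        mad_threshold = float(med + 2.0 * mad_of_mads)
    return CohortQCStats(
        mean_bin_count=float(mean_bin.mean()),
        sd_bin_count=float(mean_bin.std(ddof=1)),
        mad_threshold=mad_threshold,
    )


def compute_cell_qc(
    counts: pd.DataFrame,
    mad_threshold: float | None = None,
    stats: CohortQCStats | None = None,
) -> list[CellQCRecord]:
    """Screen every cell of a cohort on bin-count SD and derivative MAD.

    Cohort statistics are computed once on the full input and never
    re-computed after exclusions; passing ``stats`` (from
    :func:`cohort_qc_stats` on the original cohort) makes re-runs on a
    subset idempotent.  A cell is SD-flagged when its mean bin count is
    strictly outside cohort mean +/- 2 x sample SD.
    """
    if stats is None:
        stats = cohort_qc_stats(counts, mad_threshold=mad_threshold)
    mat = counts.to_numpy(dtype=float)
    mean_bin = mat.mean(axis=0)
    cohort_mean = stats.mean_bin_count
    cohort_sd = stats.sd_bin_count
    mad_threshold = stats.mad_threshold
    mads = np.array(
        [derivative_mad(_depth_normalize(mat[:, j])) for j in range(mat.shape[1])]
    )
    records = []
    for j, cell in enumerate(counts.columns):
        total = int(mat[:, j].sum())
        zero = total == 0
        sd_fail = bool(abs(mean_bin[j] - cohort_mean) > 2.0 * cohort_sd)
        mad_fail = bool(mads[j] > mad_threshold)
        records.append(
            CellQCRecord(
                cell_id=str(cell),
                total_reads=total,
                mean_bin_count=float(mean_bin[j]),
                mad=float(mads[j]),
                sd_fail=sd_fail and not zero,
                mad_fail=mad_fail and not zero,
                zero_coverage=zero,
            )
        )
    return records


def build_normal_panel(normal_counts: pd.DataFrame) -> NormalPanel:
    """Per-bin median of depth-normalized diploid profiles.

    Bins whose reference value is zero (no coverage in any normal) are
    masked; the mask propagates into every downstream log-ratio profile.
    """
    if normal_counts.shape[1] < 2:
        raise InsufficientReferenceError(
            f"panel needs >= 2 normal cells, got {normal_counts.shape[1]}"
        )
    mat = normal_counts.to_numpy(dtype=float)
    normed = np.column_stack([_depth_normalize(mat[:, j]) for j in range(mat.shape[1])])
    reference = np.median(normed, axis=1)
    mask = reference <= 0
    return NormalPanel(reference=reference, mask=mask, n_cells=mat.shape[1])


def log2_ratios(
    cell_counts: pd.Series | np.ndarray,
    panel: NormalPanel,
    cell_id: str = "",
) -> LogRatioProfile:
    """Depth-normalized log2 ratio of a cell against the normal panel.

    Zero-count bins receive a pseudocount of 0.5 reads before depth
    normalization; masked panel bins come out as NaN.  The result is
    invariant to any positive rescaling of the input counts.
    """
    col = np.asarray(cell_counts, dtype=float)
    if col.shape[0] != panel.reference.shape[0]:
        raise GridMismatchError(
            f"cell has {col.shape[0]} bins, panel has {panel.reference.shape[0]}"
        )
    col = np.where(col <= 0, PSEUDOCOUNT, col)
    # depth-normalize over unmasked bins
    m = col[~panel.mask].mean()
    if m <= 0:
        raise ValueError(f"cell {cell_id} has zero coverage on unmasked bins")
    normed = col / m
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(normed / panel.reference)
    log2[panel.mask] = np.nan
    return LogRatioProfile(cell_id=cell_id, log2=log2, mask=panel.mask.copy())
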