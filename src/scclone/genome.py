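"""Genomic bin grids for shallow single-cell WGS copy-number analysis.

Read counts from ~0.15x single-cell libraries are aggregated in fixed-width
genomic bins (50 kb by default) before any copy-number inference.  A
:class:`BinGrid` is the coordinate system shared by every downstream step:
counts, log2 ratios, segments and events all refer to its bin indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 50_000


class GenomeSpecError(ValueError):
    """Raised when chromosome lengths / arm boundaries are inconsistent."""


@dataclass
class BinGrid:
    """Fixed, non-overlapping tiling of a genome into bins.

    Parameters
    ----------
    bins :
        DataFrame with columns ``chrom``, ``start``, ``end`` (0-based,
        half-open) and ``arm`` (``"p"`` or ``"q"``), sorted by
        (chromosome, start).  All bins have width ``width`` except possibly
        the last bin of each chromosome.
    width :
        Nominal bin width in bp.
    """

    bins: pd.DataFrame
    width: int = DEFAULT_BIN_WIDTH
    _chrom_slices: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            self._chrom_slices[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def chrom_size(self, chrom: str) -> int:
        sl = self._chrom_slices[chrom]
        return int(self.bins["end"].iloc[sl.stop - 1])

    def arm_mask(self, chrom: str, arm: str) -> np.ndarray:
        """Boolean mask (over all bins) of one chromosome arm."""
        mask = np.zeros(self.n_bins, dtype=bool)
        sl = self.chrom_slice(chrom)
        arms = self.bins["arm"].to_numpy()[sl]
        mask[sl] = arms == arm
        return mask

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing base-pair position ``pos``."""
        sl = self.chrom_slice(chrom)
        starts = self.bins["start"].to_numpy()[sl]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self.bins["end"].iloc[sl.start + i]:
            raise GenomeSpecError(f"position {chrom}:{pos} outside grid")
        return sl.start + i

    def interval_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins overlapping [start, end)."""
        sl = self.chrom_slice(chrom)
        starts = self.bins["start"].to_numpy()[sl]
        ends = self.bins["end"].to_numpy()[sl]
        hit = (starts < end) & (ends > start)
        return np.nonzero(hit)[0] + sl.start

    def to_bed(self) -> pd.DataFrame:
        return self.bins[["chrom", "start", "end", "arm"]].copy()


def build_genome(
    chrom_sizes: dict[str, int],
    arm_boundaries: dict[str, int],
    width: int = DEFAULT_BIN_WIDTH,
) -> BinGrid:
    """Tile chromosomes into fixed-width bins with p/q arm labels.

    ``arm_boundaries[chrom]`` is the bp coordinate of the p/q boundary
    (centromere); bins starting before it are labelled ``p``.  The last bin
    of a chromosome absorbs any remainder shorter than ``width``.
    """
    if width <= 0:
        raise GenomeSpecError("bin width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise GenomeSpecError(f"chromosome {chrom} has non-positive length")
        boundary = arm_boundaries.get(chrom, size)
        if not (0 <= boundary <= size):
            raise GenomeSpecError(
                f"arm boundary {boundary} outside chromosome {chrom} (size {size})"
            )
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), "p" if s < boundary else "q"))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
    return BinGrid(bins=bins, width=width)


def default_genome(width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Scaled-down synthetic genome used by the simulator.

    Seven chromosomes totalling 72.5 Mb (1450 bins at 50 kb), with p/q arm
    boundaries at ~40% of each chromosome.  Chromosome sizes are chosen so
    that whole-chromosome, whole-arm, subchromosomal (>15 Mb, chr1 only) and
    focal (<15 Mb) events can all be represented while keeping per-cell
    segmentation fast.
    """
    sizes = {
        "chr1": 20_000_000,
        "chr2": 12_500_000,
        "chr3": 10_000_000,
        "chr4": 9_000_000,
        "chr5": 8_000_000,
        "chr6": 7_000_000,
        "chr7": 6_000_000,
    }
    arms = {c: int(0.4 * s) for c, s in sizes.items()}
    return build_genome(sizes, arms, width=width)
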