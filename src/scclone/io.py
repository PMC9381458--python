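"""Readers and writers for the pipeline's plain-text interchange formats.

Bins travel as BED (chrom, start, end, arm); counts as a TSV matrix with
BED-prefixed rows and cell-id columns; metadata and genotypes as TSV;
segments in SEG format (1-based inclusive coordinates, ``num.mark`` and
``seg.mean`` columns, plus an integer ``CN`` extension); trees as Newick.
Writers emit a provenance header (``# scclone ...``) recording the package
version and the run seed; readers are gzip-transparent and skip ``#``
comment lines.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .genome import BinGrid
from .segment import CNVEvent, Segment


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def provenance_header(seed: int | None = None, extra: str = "") -> str:
    parts = [f"# scclone v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return " ".join(parts) + "\n"


def write_bed(grid: BinGrid, path, seed: int | None = None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed, "format=bed"))
        grid.to_bed().to_csv(fh, sep="\t", header=False, index=False)


def read_bed_grid(path, width: int | None = None) -> BinGrid:
    bins = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "arm"],
        dtype={"chrom": str, "start": int, "end": int, "arm": str},
    )
    if width is None:
        width = int((bins["end"] - bins["start"]).max())
    return BinGrid(bins=bins, width=width)


def write_counts(
    counts: pd.DataFrame, grid: BinGrid, path, seed: int | None = None
) -> None:
    """Counts TSV: rows = bins (BED-prefixed), columns = cell ids."""
    out = pd.concat(
        [grid.bins[["chrom", "start", "end"]].reset_index(drop=True),
         counts.reset_index(drop=True)],
        axis=1,
    )
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed, "format=counts"))
        out.to_csv(fh, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (counts, bin coordinates) from a counts TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    coords = df[["chrom", "start", "end"]]
    counts = df.drop(columns=["chrom", "start", "end"])
    return counts, coords


def write_table(df: pd.DataFrame, path, seed: int | None = None, kind: str = "table") -> None:
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed, f"format={kind}"))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_seg(
    cell_segments: dict[str, list[Segment]], path, seed: int | None = None
) -> None:
    """SEG format: sample, chrom, loc.start, loc.end, num.mark, seg.mean, CN.

    Coordinates are 1-based inclusive, following the SEG convention.
    """
    rows = []
    for cell in sorted(cell_segments):
        for s in cell_segments[cell]:
            rows.append(
                {
                    "ID": cell,
                    "chrom": s.chrom,
                    "loc.start": s.start_bp + 1,
                    "loc.end": s.end_bp,
                    "num.mark": s.n_bins,
                    "seg.mean": round(s.mean_log2, 6),
                    "CN": s.cn,
                }
            )
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed, "format=seg"))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_seg(path) -> dict[str, list[Segment]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[Segment]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["ID"]), []).append(
            Segment(
                chrom=str(row["chrom"]),
                start_bin=-1,
                end_bin=-1,
                start_bp=int(row["loc.start"]) - 1,
                end_bp=int(row["loc.end"]),
                mean_log2=float(row["seg.mean"]),
                n_bins=int(row["num.mark"]),
                cn=int(row["CN"]) if pd.notna(row.get("CN")) else None,
            )
        )
    return out


def write_events(
    events: list[CNVEvent], path_tsv, path_json=None, seed: int | None = None
) -> None:
    rows = [
        {
            "chrom": ev.chrom,
            "start": ev.start_bp,
            "end": ev.end_bp,
            "direction": ev.direction,
            "CN": ev.cn,
            "scale": ev.scale,
            "n_cells": ev.n_cells,
            "region_counts": json.dumps(ev.region_counts, sort_keys=True),
        }
        for ev in events
    ]
    write_table(pd.DataFrame(rows), path_tsv, seed=seed, kind="events")
    if path_json is not None:
        payload = [
            {
                "chrom": ev.chrom,
                "start": ev.start_bp,
                "end": ev.end_bp,
                "direction": ev.direction,
                "cn": ev.cn,
                "scale": ev.scale,
                "cells": ev.cells,
                "region_counts": ev.region_counts,
            }
            for ev in events
        ]
        Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")


def write_newick(newick: str, path, seed: int | None = None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed, "format=newick"))
        fh.write(newick.rstrip() + "\n")


def read_newick(path) -> str:
    lines = [
        l.strip() for l in _open_text(path).read().splitlines()
        if l.strip() and not l.startswith("#")
    ]
    return lines[0]
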