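"""End-to-end orchestration: QC -> normalize -> segment -> clones ->
clonality -> phylogeny/evolution -> spatial, per tumour, plus cohort-level
association tests.

The per-tumour entry point :func:`analyse_tumour` works on in-memory
DataFrames (counts, metadata, genotypes) so it can be driven equally by
the synthetic generator, by tests, or by :func:`run_pipeline`, which adds
file I/O around it.  Every stage logs cells in/out; all randomness derives
from a single seed, so a fixed config + seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scio
from .clonality import (
    AnnotatedEvent,
    annotate_biomarkers,
    annotate_mutation,
    assign_clonality,
    integrate_mutations,
)
from .clones import (
    Clone,
    build_segment_matrix,
    enforce_min_clone_size,
    choose_k,
    cluster_cells,
    define_clones,
    detection_sensitivity,
    pca_kmeans_check,
    substructure_category,
)
from .genome import BinGrid
from .phylo import (
    EvolutionCall,
    TreeNode,
    classify_evolution,
    clone_distance_matrix,
    fishplot_table,
    nj_tree,
    root_tree,
    to_newick,
)
from .qc import build_normal_panel, compute_cell_qc, log2_ratios
from .segment import CNVEvent, consolidate_cnvs, segment_profile
from .spatial import SpatialTestResult, fisher_exact_2x2, fisher_exact_rxc, spatial_report

logger = logging.getLogger("scclone")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults."""

    counts: str | None = None
    bins: str | None = None
    metadata: str | None = None
    genotypes: str | None = None
    biomarkers: str | None = None
    output_dir: str = "scclone_out"
    bin_width: int = 50_000
    cbs_alpha: float = 1e-5
    cbs_permutations: int = 1000
    max_permutations: int = 100_000
    merge_p: float = 0.01
    cn_mode: str = "rounding"
    min_supporting_cells: int = 3
    overlap_tolerance_bins: int = 2
    min_reciprocal_overlap: float = 0.8
    k_max: int = 6
    presence_fraction: float = 0.5
    dropout: float = 0.2
    p_threshold: float = 0.05
    subgroups: dict = field(default_factory=dict)  # tumour id -> subgroup
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class TumourReport:
    tumour_id: str
    n_cells_in: int
    n_cells_pass: int
    purity: float
    category: str  # none | moderate | extensive
    clones: list[Clone]
    chosen_k: int
    k_votes: dict
    pca_kmeans_ari: float
    events: list[AnnotatedEvent]
    mutations: list[AnnotatedEvent]
    evolution: EvolutionCall
    tree: TreeNode | None
    newick: str | None
    fractions: pd.DataFrame | None
    spatial: list[SpatialTestResult]
    sensitivity_pct: float
    cell_segments: dict = field(default_factory=dict)
    cell_clusters: dict = field(default_factory=dict)

    @property
    def n_tumour_clones(self) -> int:
        return sum(1 for c in self.clones if not c.is_normal)


def analyse_tumour(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    grid: BinGrid,
    genotypes: pd.DataFrame | None = None,
    biomarker_table: pd.DataFrame | None = None,
    subgroup: str | None = None,
    config: PipelineConfig | None = None,
    tumour_id: str | None = None,
) -> TumourReport:
    """Run the full single-tumour analysis on in-memory inputs.

    ``counts`` holds all cells (columns) over ``grid`` bins (rows);
    ``metadata`` must carry ``cell_id``, ``region`` and ``origin`` —
    cells with ``origin == "normal_reference"`` form the copy-number
    reference panel, all others are the tumour sample.
    """
    cfg = config or PipelineConfig()
    if tumour_id is None:
        tum = metadata.loc[metadata["origin"] != "normal_reference", "tumour"]
        tumour_id = str(tum.iloc[0]) if len(tum) else "tumour"

    ref_ids = metadata.loc[metadata["origin"] == "normal_reference", "cell_id"].tolist()
    sample_ids = metadata.loc[metadata["origin"] != "normal_reference", "cell_id"].tolist()
    if len(ref_ids) < 2:
        raise ValueError("need >= 2 normal reference cells for the panel")

    # --- QC ------------------------------------------------------------
    sample_qc = compute_cell_qc(counts[sample_ids])
    passing = [r.cell_id for r in sample_qc if r.passed]
    logger.info(
        "%s QC: cells_in=%d cells_passing=%d cells_failed=%d",
        tumour_id, len(sample_ids), len(passing), len(sample_ids) - len(passing),
    )
    assert len(passing) + sum(1 for r in sample_qc if not r.passed) == len(sample_ids)

    ref_qc = compute_cell_qc(counts[ref_ids])
    ref_pass = [r.cell_id for r in ref_qc if r.passed]
    if len(ref_pass) < 2:
        ref_pass = ref_ids
    panel = build_normal_panel(counts[ref_pass])
    logger.info("%s panel: %d/%d reference cells", tumour_id, len(ref_pass), len(ref_ids))

    # --- normalize + segment -------------------------------------------
    rng = np.random.default_rng(cfg.seed)
    cell_segments = {}
    for cell in passing:
        prof = log2_ratios(counts[cell], panel, cell_id=cell)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        cell_segments[cell] = segment_profile(
            prof.values,
            grid,
            alpha=cfg.cbs_alpha,
            n_permutations=min(cfg.cbs_permutations, cfg.max_permutations),
            seed=cell_seed,
            cn_mode=cfg.cn_mode,
            merge_p=cfg.merge_p,
        )
    regions = dict(zip(metadata["cell_id"], metadata["region"]))
    events = consolidate_cnvs(
        cell_segments,
        grid,
        tol_bins=cfg.overlap_tolerance_bins,
        min_overlap=cfg.min_reciprocal_overlap,
        min_cells=cfg.min_supporting_cells,
        cell_regions=regions,
    )
    logger.info("%s segmentation: %d cells, %d consolidated events",
                tumour_id, len(cell_segments), len(events))

    # --- clones ---------------------------------------------------------
    matrix = build_segment_matrix(cell_segments)
    k, votes = choose_k(matrix, k_max=cfg.k_max, seed=cfg.seed)
    labels = cluster_cells(matrix, k)
    labels = enforce_min_clone_size(labels, matrix, cfg.min_supporting_cells)
    ari, _flag = pca_kmeans_check(matrix, k, seed=cfg.seed)
    clones, purity = define_clones(labels, matrix, cell_regions=regions)
    n_tumour = sum(1 for c in clones if not c.is_normal)
    if n_tumour == 0:
        logger.warning("%s: all clusters diploid; treating largest as the tumour clone "
                       "is NOT done — purity is 0", tumour_id)
        category = "none"
    else:
        category = substructure_category(n_tumour)
    logger.info("%s clones: k=%d votes=%s purity=%.2f category=%s",
                tumour_id, k, votes, purity, category)

    # --- clonality ------------------------------------------------------
    annotated: list[AnnotatedEvent] = []
    if n_tumour:
        for ev in events:
            annotated.append(
                assign_clonality(ev, clones, presence_fraction=cfg.presence_fraction)
            )
    mut_annotated: list[AnnotatedEvent] = []
    if genotypes is not None and len(genotypes) and n_tumour:
        geno = genotypes[genotypes["cell_id"].isin(passing)]
        statuses = integrate_mutations(geno, clones, dropout=cfg.dropout)
        mut_annotated = [annotate_mutation(s, clones) for s in statuses]
    if biomarker_table is not None and subgroup:
        annotate_biomarkers(annotated + mut_annotated, subgroup, biomarker_table)

    # --- phylogeny & evolution ------------------------------------------
    tree = None
    newick = None
    evolution = EvolutionCall("no_evolution", max(n_tumour, 1), {"n_clones": n_tumour})
    fractions = None
    if n_tumour >= 1:
        D = clone_distance_matrix(clones, matrix.weights)
        if len(D) >= 3:
            tree = root_tree(nj_tree(D))
        else:
            # two taxa: trivial rooted tree
            d = float(D.iloc[0, 1])
            tree = TreeNode(children=[
                TreeNode(name=D.index[1], length=d / 2),
                TreeNode(name=D.index[0], length=d / 2),
            ])
            tree.children.sort(key=lambda c: (c.name != "normal", c.name))
        newick = to_newick(tree)
        evolution = classify_evolution(clones, tree, annotated)
        fractions = fishplot_table(clones, tree)
    logger.info("%s evolution: %s", tumour_id, evolution.mode)

    # --- spatial ---------------------------------------------------------
    spatial: list[SpatialTestResult] = []
    sample_regions = {c: r for c, r in regions.items() if c in passing}
    region_names = sorted(set(sample_regions.values()))
    if len(region_names) == 2:
        spatial = spatial_report(
            clones, events, sample_regions, regions=tuple(region_names)
        )
    else:
        logger.info("%s: spatial analysis skipped (%d region(s))",
                    tumour_id, len(region_names))

    sens = detection_sensitivity(len(passing), cfg.min_supporting_cells)
    return TumourReport(
        tumour_id=tumour_id,
        n_cells_in=len(sample_ids),
        n_cells_pass=len(passing),
        purity=purity,
        category=category,
        clones=clones,
        chosen_k=k,
        k_votes=votes,
        pca_kmeans_ari=ari,
        events=annotated,
        mutations=mut_annotated,
        evolution=evolution,
        tree=tree,
        newick=newick,
        fractions=fractions,
        spatial=spatial,
        sensitivity_pct=sens,
        cell_segments=cell_segments,
        cell_clusters=dict(zip(matrix.cells, labels.tolist())),
    )


def run_pipeline(config: PipelineConfig) -> list[TumourReport]:
    """File-driven run: read inputs, analyse each tumour, write outputs."""
    if not config.counts or not config.metadata:
        raise ValueError("config must provide counts and metadata paths")
    counts, coords = scio.read_counts(config.counts)
    if config.bins:
        grid = scio.read_bed_grid(config.bins, width=config.bin_width)
    else:
        coords = coords.copy()
        coords["arm"] = "q"
        grid = BinGrid(bins=coords, width=config.bin_width)
    metadata = scio.read_table(config.metadata)
    genotypes = scio.read_table(config.genotypes) if config.genotypes else None
    biomarkers = scio.read_table(config.biomarkers) if config.biomarkers else None

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    ref_meta = metadata[metadata["origin"] == "normal_reference"]
    reports = []
    tumour_ids = [
        t for t in metadata["tumour"].unique()
        if (metadata.loc[metadata["tumour"] == t, "origin"] != "normal_reference").any()
    ]
    for tumour in tumour_ids:
        sub_meta = pd.concat(
            [metadata[(metadata["tumour"] == tumour)], ref_meta]
        ).drop_duplicates("cell_id")
        sub_counts = counts[sub_meta["cell_id"].tolist()]
        sub_geno = (
            genotypes[genotypes["cell_id"].isin(sub_meta["cell_id"])]
            if genotypes is not None
            else None
        )
        report = analyse_tumour(
            sub_counts,
            sub_meta,
            grid,
            genotypes=sub_geno,
            biomarker_table=biomarkers,
            subgroup=config.subgroups.get(str(tumour)),
            config=config,
            tumour_id=str(tumour),
        )
        reports.append(report)
        _write_report(report, outdir, config.seed)
    summary = summarize_cohort(reports)
    scio.write_table(summary, outdir / "cohort_summary.tsv", seed=config.seed,
                     kind="cohort-summary")
    return reports


def _write_report(report: TumourReport, outdir: Path, seed: int) -> None:
    tdir = outdir / report.tumour_id
    tdir.mkdir(parents=True, exist_ok=True)
    scio.write_seg(report.cell_segments, tdir / "segments.seg", seed=seed)
    scio.write_events(
        [a.event for a in report.events],
        tdir / "events.tsv",
        tdir / "events.json",
        seed=seed,
    )
    if report.newick:
        scio.write_newick(report.newick, tdir / "clone_tree.nwk", seed=seed)
    if report.fractions is not None:
        scio.write_table(report.fractions, tdir / "clone_fractions.tsv", seed=seed,
                         kind="fishplot-fractions")
    clone_rows = [
        {
            "clone": c.clone_id,
            "n_cells": c.size,
            "is_normal": c.is_normal,
            **{f"n_{r}": n for r, n in sorted(c.region_counts.items())},
        }
        for c in report.clones
    ]
    scio.write_table(pd.DataFrame(clone_rows), tdir / "clones.tsv", seed=seed,
                     kind="clones")
    if report.spatial:
        rows = [
            {
                "test_id": s.test_id,
                "unit": s.unit,
                "p": s.p,
                "q": s.q,
                "significant": s.significant,
                "region_specific": s.region_specific,
            }
            for s in report.spatial
        ]
        scio.write_table(pd.DataFrame(rows), tdir / "spatial_tests.tsv", seed=seed,
                         kind="spatial")


def summarize_cohort(reports: list[TumourReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tumour": r.tumour_id,
                "cells_in": r.n_cells_in,
                "cells_pass": r.n_cells_pass,
                "purity_pct": round(100 * r.purity, 1),
                "n_clones": r.n_tumour_clones,
                "category": r.category,
                "mode": r.evolution.mode,
                "sensitivity_pct": round(r.sensitivity_pct, 1),
            }
            for r in reports
        ]
    )


def mean_cells_per_tumour(total_passing_cells: int, n_tumours: int) -> float:
    """Mean analysed cells per tumour for a cohort."""
    if n_tumours <= 0:
        raise ValueError("n_tumours must be positive")
    return total_passing_cells / n_tumours


def cohort_association_tests(cohort: pd.DataFrame) -> dict:
    """Risk-group association tests over a cohort summary.

    ``cohort`` needs columns ``tumour``, ``category`` (none / moderate /
    extensive), ``risk`` (favourable / standard / high / very_high) and
    optionally ``mode``.  Returns exact p-values for (a) wholly-clonal
    (no substructure) x favourable-risk, (b) extensive substructure x
    very-high-risk, and (c) the substructure x evolution-mode r x c table.
    Tumours without a risk label are dropped with a warning.
    """
    df = cohort.copy()
    missing = df["risk"].isna() if "risk" in df else pd.Series(True, index=df.index)
    if missing.any():
        logger.warning("dropping %d tumours without risk labels", int(missing.sum()))
        df = df[~missing]
    fav = df["risk"] == "favourable"
    clonal = df["category"] == "none"
    t_clonal = np.array(
        [
            [int((fav & clonal).sum()), int((fav & ~clonal).sum())],
            [int((~fav & clonal).sum()), int((~fav & ~clonal).sum())],
        ]
    )
    vhr = df["risk"] == "very_high"
    ext = df["category"] == "extensive"
    t_ext = np.array(
        [
            [int((vhr & ext).sum()), int((vhr & ~ext).sum())],
            [int((~vhr & ext).sum()), int((~vhr & ~ext).sum())],
        ]
    )
    out = {
        "clonal_vs_favourable": {
            "table": t_clonal,
            "p": fisher_exact_2x2(t_clonal),
        },
        "extensive_vs_very_high": {
            "table": t_ext,
            "p": fisher_exact_2x2(t_ext),
        },
    }
    if "mode" in df:
        cats = ["none", "moderate", "extensive"]
        modes = ["no_evolution", "punctuated", "gradual_branching"]
        t_mode = np.array(
            [
                [int(((df["category"] == c) & (df["mode"] == m)).sum()) for m in modes]
                for c in cats
            ]
        )
        out["category_vs_mode"] = {"table": t_mode, "p": fisher_exact_rxc(t_mode)}
    return out
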