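"""Synthetic single-cell shallow-WGS data with exported ground truth.

The generator emulates the data-generating process of a FACS-sorted,
WGA-amplified, shallow-sequenced (~0.15x, ~50 reads per 50 kb bin) tumour
cohort: each tumour carries 1-4 aneuploid clones related by a clone tree,
mixed with a small fraction of normal diploid cells, sampled from two
spatially distinct regions (``r1``/``r2``) that may differ in clone
content.  Per-cell read counts over a :class:`~scclone.genome.BinGrid` are
drawn from a negative-binomial model with a per-cell lognormal bin-level
amplification factor (WGA noise); a configurable fraction of cells are
low-quality outliers with inflated noise.  Heterozygous mutation genotypes
(Sanger-style presence/absence) are subject to allelic dropout.

GC/mappability bias is not simulated: the pipeline's panel-of-normals
normalization would divide it out, so it would be invisible downstream.
Doublets and read-level artefacts are likewise out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid

REGIONS = ("r1", "r2")
MAX_CN = 8


class CloneTreeError(ValueError):
    """Invalid clone tree: cycles, orphans, multiple roots."""


class CloneFractionError(ValueError):
    """Per-region clone fractions exceed 1."""


@dataclass
class TrueEvent:
    """A ground-truth copy-number event carried by a clone (and heirs)."""

    chrom: str
    start: int
    end: int
    cn: int  # absolute integer copy number over the interval
    epoch: str = "initiation"  # "initiation" | "later"

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.cn)


@dataclass
class CloneSpec:
    """Declarative description of one clone in a tumour's clone tree.

    ``parent is None`` marks the founding clone (child of the implicit
    diploid ancestor); every tumour has exactly one.  ``events`` are the
    alterations this clone adds on top of (or reverts from) its parent's
    state; the materialized profile inherits the parent profile and then
    applies them.  ``fractions`` give the clone's share of cells in each
    sampled region; per region the clone fractions may sum to < 1, the
    remainder being normal diploid cells.
    """

    clone_id: str
    parent: str | None
    events: list[TrueEvent] = field(default_factory=list)
    mutations: list[str] = field(default_factory=list)
    fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class ValidatedClone:
    clone_id: str
    parent: str | None
    profile: np.ndarray  # per-bin absolute CN
    events: list[TrueEvent]  # own + inherited
    own_events: list[TrueEvent]
    mutations: list[str]  # own + inherited
    fractions: dict[str, float]


@dataclass
class SimulationParams:
    """Noise and sampling parameters of the generator.

    ``reads_per_bin`` defaults to 50, matching ~0.15x coverage with 150 bp
    reads in 50 kb bins.  ``nb_dispersion`` is the negative-binomial size
    parameter (larger = closer to Poisson); ``wga_sd`` the log-scale SD of
    the per-cell, per-bin lognormal amplification factor.  Together the
    defaults put the per-bin log2-ratio SD of a diploid bin near 0.24, a
    mildly overdispersed shallow-WGA regime in which < 5% of diploid bins
    stray beyond |log2| = 0.5.  ``depth_sd`` is the log-scale SD of a
    per-cell library-size factor: real single-cell libraries are sequenced
    to a per-cell read target with substantial technical spread, so total
    depth varies between cells independently of ploidy (depth-normalization
    cancels it downstream; the bin-count QC filter screens its tails).
    """

    cells_per_region: int = 40
    reads_per_bin: float = 50.0
    nb_dispersion: float = 250.0
    wga_sd: float = 0.04
    depth_sd: float = 0.15
    outlier_fraction: float = 0.05
    outlier_noise_mult: float = 8.0
    dropout: float = 0.2
    missing_rate: float = 0.0
    n_reference_normals: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("outlier_fraction", "dropout", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_bin <= 0:
            raise ValueError("reads_per_bin must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Exported truth for scoring inference against the simulation."""

    cell_clone: pd.Series  # cell id -> clone id ("normal" for diploid cells)
    cell_region: pd.Series
    events: list[TrueEvent]
    purity: dict[str, float]  # region -> tumour-cell fraction; "all" pooled
    mode: str | None = None  # expected evolution mode, if declared
    clones: list[ValidatedClone] = field(default_factory=list)


def validate_clone_truth(
    clones: list[CloneSpec], grid: BinGrid
) -> list[ValidatedClone]:
    """Resolve the clone tree and materialize per-bin CN profiles.

    Children inherit the parent's profile and then apply their own events.
    Rejects cycles, unresolvable parents, multiple/absent roots, copy
    numbers outside [0, 8], and per-region fractions summing above 1.
    """
    by_id = {c.clone_id: c for c in clones}
    if len(by_id) != len(clones):
        raise CloneTreeError("duplicate clone ids")
    roots = [c for c in clones if c.parent is None]
    if len(roots) != 1:
        raise CloneTreeError(f"expected exactly one root clone, got {len(roots)}")
    for c in clones:
        if c.parent is not None and c.parent not in by_id:
            raise CloneTreeError(f"clone {c.clone_id} has unknown parent {c.parent}")

    # topological order with cycle detection
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(cid: str, stack: list[str]) -> None:
        if state.get(cid) == 2:
            return
        if cid in stack:
            raise CloneTreeError(f"cycle through clone {cid}")
        c = by_id[cid]
        if c.parent is not None:
            visit(c.parent, stack + [cid])
        if state.get(cid) != 2:
            state[cid] = 2
            order.append(cid)

    for c in clones:
        visit(c.clone_id, [])

    for region in REGIONS:
        tot = sum(c.fractions.get(region, 0.0) for c in clones)
        if tot > 1.0 + 1e-9:
            raise CloneFractionError(
                f"clone fractions in {region} sum to {tot:.3f} > 1"
            )

    validated: dict[str, ValidatedClone] = {}
    for cid in order:
        c = by_id[cid]
        if c.parent is None:
            profile = np.full(grid.n_bins, 2, dtype=np.int16)
            inherited_events: list[TrueEvent] = []
            inherited_mut: list[str] = []
        else:
            p = validated[c.parent]
            profile = p.profile.copy()
            inherited_events = list(p.events)
            inherited_mut = list(p.mutations)
        for ev in c.events:
            if not 0 <= ev.cn <= MAX_CN:
                raise ValueError(f"copy number {ev.cn} outside [0, {MAX_CN}]")
            idx = grid.interval_bins(ev.chrom, ev.start, ev.end)
            profile[idx] = ev.cn
        # a reverting event (back to CN2) removes the inherited event it undoes
        events = [
            e
            for e in inherited_events
            if not any(
                e.chrom == ev.chrom
                and ev.start <= e.start
                and e.end <= ev.end
                and ev.cn == 2
                for ev in c.events
            )
        ] + [e for e in c.events if e.cn != 2]
        validated[cid] = ValidatedClone(
            clone_id=cid,
            parent=c.parent,
            profile=profile,
            events=events,
            own_events=list(c.events),
            mutations=inherited_mut + [m for m in c.mutations if m not in inherited_mut],
            fractions=dict(c.fractions),
        )
    return [validated[cid] for cid in order]


def largest_remainder_allocation(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of ``n`` items proportional to ``fractions``.

    Deterministic largest-remainder rounding; ``fractions`` need not sum to
    one (they are renormalized).  Ties in remainder break toward the lower
    index, so the allocation is reproducible.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.sum() <= 0:
        raise ValueError("fractions must have positive sum")
    quotas = fractions / fractions.sum() * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    # stable sort => ties broken toward lower index
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_cells(
    grid: BinGrid,
    truth: list[ValidatedClone],
    params: SimulationParams,
    tumour_id: str = "T1",
    expected_mode: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw per-cell bin counts, metadata and mutation genotypes.

    Returns ``(counts, metadata, genotypes, ground_truth)`` where
    ``counts`` is a bins x cells integer DataFrame (rows aligned with
    ``grid.bins``), ``metadata`` has one row per cell (``cell_id``,
    ``tumour``, ``region``, ``origin``, ``true_clone``) and ``genotypes``
    is long-form (``cell_id``, ``mutation``, ``call``) with calls in
    {present, absent, missing}.

    Counts for cell *c* of clone *k* in bin *b* follow
    ``NegBin(mean = reads_per_bin * CN_kb / 2 * g_cb, size = nb_dispersion)``
    with ``g_cb`` lognormal (sd ``wga_sd``); outlier cells have their WGA
    noise multiplied by ``outlier_noise_mult``.  A clone's heterozygous
    mutations are observed as absent with probability ``dropout`` per cell
    per site.  Reference normal diploid cells (a sequencing-batch control
    panel) are appended with ``tumour="control"``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.cells_per_region <= 0:
        raise ValueError("cells_per_region must be positive")

    clone_ids = [c.clone_id for c in truth]
    profiles = {c.clone_id: c.profile for c in truth}
    diploid = np.full(grid.n_bins, 2, dtype=np.int16)

    assignments: list[tuple[str, str]] = []  # (clone or "normal", region)
    for region in REGIONS:
        fracs = np.array([c.fractions.get(region, 0.0) for c in truth])
        normal_frac = max(0.0, 1.0 - fracs.sum())
        alloc = largest_remainder_allocation(
            np.append(fracs, normal_frac), params.cells_per_region
        )
        labels = clone_ids + ["normal"]
        region_cells = [
            (labels[i], region) for i in range(len(labels)) for _ in range(alloc[i])
        ]
        rng.shuffle(region_cells)
        assignments.extend(region_cells)

    cell_ids = [f"{tumour_id}_c{i:03d}" for i in range(len(assignments))]
    n_outliers = int(round(params.outlier_fraction * len(assignments)))
    outlier_idx = set(
        rng.choice(len(assignments), size=n_outliers, replace=False).tolist()
        if n_outliers
        else []
    )

    def draw_cell(cn_profile: np.ndarray, noise_mult: float = 1.0) -> np.ndarray:
        depth = rng.lognormal(mean=0.0, sigma=params.depth_sd)
        g = rng.lognormal(mean=0.0, sigma=params.wga_sd * noise_mult, size=grid.n_bins)
        mean = depth * params.reads_per_bin * cn_profile / 2.0 * g
        size = params.nb_dispersion / noise_mult
        # numpy NB: n = size, p = size / (size + mean)
        p = size / (size + np.maximum(mean, 1e-12))
        return rng.negative_binomial(size, p).astype(np.int32)

    counts = np.empty((grid.n_bins, len(assignments)), dtype=np.int32)
    for j, (clone, _region) in enumerate(assignments):
        prof = diploid if clone == "normal" else profiles[clone]
        mult = params.outlier_noise_mult if j in outlier_idx else 1.0
        counts[:, j] = draw_cell(prof, mult)

    meta_rows = [
        {
            "cell_id": cid,
            "tumour": tumour_id,
            "region": region,
            "origin": "tumour_sample",
            "true_clone": clone,
        }
        for cid, (clone, region) in zip(cell_ids, assignments)
    ]

    # reference panel of normal diploid cells (separate control batch)
    ref_counts = np.empty((grid.n_bins, params.n_reference_normals), dtype=np.int32)
    for j in range(params.n_reference_normals):
        ref_counts[:, j] = draw_cell(diploid)
    ref_ids = [f"{tumour_id}_n{i:03d}" for i in range(params.n_reference_normals)]
    meta_rows += [
        {
            "cell_id": cid,
            "tumour": "control",
            "region": "control",
            "origin": "normal_reference",
            "true_clone": "normal",
        }
        for cid in ref_ids
    ]

    all_ids = cell_ids + ref_ids
    counts_df = pd.DataFrame(
        np.hstack([counts, ref_counts]), columns=all_ids, index=grid.bins.index
    )
    metadata = pd.DataFrame(meta_rows)

    mutations = sorted({m for c in truth for m in c.mutations})
    clone_mut = {c.clone_id: set(c.mutations) for c in truth}
    geno_rows = []
    for cid, (clone, _region) in zip(cell_ids, assignments):
        carried = clone_mut.get(clone, set())
        for m in mutations:
            if rng.random() < params.missing_rate:
                call = "missing"
            elif m in carried:
                call = "absent" if rng.random() < params.dropout else "present"
            else:
                call = "absent"
            geno_rows.append({"cell_id": cid, "mutation": m, "call": call})
    genotypes = pd.DataFrame(geno_rows, columns=["cell_id", "mutation", "call"])

    cell_clone = pd.Series(
        [clone for clone, _ in assignments] + ["normal"] * params.n_reference_normals,
        index=all_ids,
        name="true_clone",
    )
    cell_region = pd.Series(
        [region for _, region in assignments] + ["control"] * params.n_reference_normals,
        index=all_ids,
        name="region",
    )
    purity = {}
    for region in REGIONS:
        in_region = [c for (c, r) in assignments if r == region]
        purity[region] = (
            sum(1 for c in in_region if c != "normal") / len(in_region)
            if in_region
            else float("nan")
        )
    purity["all"] = sum(1 for c, _ in assignments if c != "normal") / len(assignments)

    event_map: dict[tuple, TrueEvent] = {}
    for c in truth:
        for e in c.events:
            event_map.setdefault(e.key(), e)
    gt = GroundTruth(
        cell_clone=cell_clone,
        cell_region=cell_region,
        events=list(event_map.values()),
        purity=purity,
        mode=expected_mode,
        clones=truth,
    )
    return counts_df, metadata, genotypes, gt


# ---------------------------------------------------------------------------
# Archetype clone trees mirroring the three tumour categories the pipeline
# is designed to resolve: no substructure (favourable-risk-like), moderate
# substructure with a punctuated burst, and extensive substructure with
# gradual branching (very-high-risk-like).
# ---------------------------------------------------------------------------


def _ev(chrom: str, start: int, end: int, cn: int, epoch: str = "initiation") -> TrueEvent:
    return TrueEvent(chrom, start, end, cn, epoch)


def favourable_archetype(purity: float = 0.95) -> list[CloneSpec]:
    """Single stable clone: driver-like events at initiation, no subclones."""
    f = purity
    return [
        CloneSpec(
            "A",
            None,
            events=[
                _ev("chr6", 0, 7_000_000, 1),  # whole-chromosome loss
                _ev("chr2", 0, 12_500_000, 3),  # whole-chromosome gain
            ],
            mutations=["CTNNB1"],
            fractions={"r1": f, "r2": f},
        )
    ]


def punctuated_archetype(purity: float = 0.9) -> list[CloneSpec]:
    """Two sibling clones sharing early events, each with a private CNV."""
    return [
        CloneSpec(
            "F",
            None,
            events=[
                _ev("chr2", 0, 12_500_000, 3),
                _ev("chr5", 0, 8_000_000, 1),
            ],
            mutations=[],
            fractions={},  # unobserved founder
        ),
        CloneSpec(
            "A",
            "F",
            events=[_ev("chr4", 0, 9_000_000, 3, epoch="later")],
            mutations=["DDX3X"],
            fractions={"r1": purity * 0.6, "r2": purity * 0.55},
        ),
        CloneSpec(
            "B",
            "F",
            events=[_ev("chr6", 0, 7_000_000, 1, epoch="later")],
            mutations=["KMT2D"],
            fractions={"r1": purity * 0.4, "r2": purity * 0.45},
        ),
    ]


def gradual_archetype(purity: float = 0.9) -> list[CloneSpec]:
    """Nested clone chain with a lost CNV: ongoing instability."""
    return [
        CloneSpec(
            "A",
            None,
            events=[
                _ev("chr3", 0, 10_000_000, 1),
                _ev("chr2", 0, 12_500_000, 3),
                _ev("chr6", 0, 7_000_000, 1),
            ],
            mutations=["TP53"],
            fractions={"r1": purity * 0.45, "r2": purity * 0.50},
        ),
        CloneSpec(
            "B",
            "A",
            events=[_ev("chr4", 0, 9_000_000, 3, epoch="later")],
            mutations=["MYC_amp"],
            fractions={"r1": purity * 0.35, "r2": purity * 0.30},
        ),
        CloneSpec(
            "C",
            "B",
            events=[
                _ev("chr7", 0, 6_000_000, 3, epoch="later"),
                _ev("chr6", 0, 7_000_000, 2, epoch="later"),  # loss reverted
            ],
            mutations=[],
            fractions={"r1": purity * 0.20, "r2": purity * 0.20},
        ),
    ]


def three_clone_archetype(purity: float = 0.9) -> list[CloneSpec]:
    """Three well-separated sibling-and-nested clones at 50/30/20% of tumour."""
    return [
        CloneSpec(
            "A",
            None,
            events=[
                _ev("chr2", 0, 12_500_000, 3),
                _ev("chr5", 0, 8_000_000, 1),
            ],
            mutations=["PTCH1"],
            fractions={"r1": purity * 0.5, "r2": purity * 0.5},
        ),
        CloneSpec(
            "B",
            "A",
            events=[_ev("chr4", 0, 9_000_000, 3, epoch="later")],
            mutations=[],
            fractions={"r1": purity * 0.3, "r2": purity * 0.3},
        ),
        CloneSpec(
            "C",
            "A",
            events=[_ev("chr6", 0, 7_000_000, 1, epoch="later")],
            mutations=[],
            fractions={"r1": purity * 0.2, "r2": purity * 0.2},
        ),
    ]
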