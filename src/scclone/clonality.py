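"""Clonal/subclonal assignment of CNV events and mutations across clones.

A CNV event counts as present in a clone when its supporting cells cover
at least half of the clone's members (copy-number dropout at ~0.15x makes
single-cell misses common, so unanimity is not required); it is *clonal*
when present in every tumour clone and *subclonal* otherwise.  Mutations,
genotyped per cell by Sanger-style presence/absence, count as present in a
clone when at least one member is positive: whole-genome amplification
drops out one allele at random, so false negatives are expected but false
positives are not.  The probability that a truly present heterozygous
mutation shows no positive call in a clone of m cells is delta**m
(dropout rate delta), reported alongside each absent call for
interpretation.

Events and mutations can additionally be annotated against a user-supplied
biomarker table; a marker is only flagged when the tumour's molecular
subgroup matches the marker's subgroup context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clones import Clone
from .segment import CNVEvent


class OrphanEventError(ValueError):
    """Event has no supporting cells among the clustered cells."""


class IdMismatchError(ValueError):
    """Genotype table refers to unknown cell ids."""


class BiomarkerTableError(ValueError):
    pass


@dataclass
class MutationStatus:
    mutation: str
    clone_status: dict[str, str]  # clone id -> present | absent | indeterminate
    clonality: str  # clonal | subclonal
    cell_frequency: float  # positive cells / tumour cells
    miss_probability: dict[str, float] = field(default_factory=dict)


@dataclass
class AnnotatedEvent:
    event: object  # CNVEvent | MutationStatus
    kind: str  # "cnv" | "mutation"
    clonality: str
    epoch: str  # "initiation" | "later"
    clone_presence: dict[str, bool] = field(default_factory=dict)
    cell_frequency: float = float("nan")
    biomarker: str | None = None
    subgroup_context: str | None = None


def assign_clonality(
    event: CNVEvent,
    clones: list[Clone],
    presence_fraction: float = 0.5,
) -> AnnotatedEvent:
    """Clonal/subclonal status of a CNV event across tumour clones.

    Present-in-clone requires supporters covering >= ``presence_fraction``
    of the clone's members; clonal means present in *all* tumour clones.
    Adding a supporting cell can only move an event toward clonal, never
    away from it.  Epoch is ``initiation`` iff clonal.
    """
    tumour = [c for c in clones if not c.is_normal]
    if not tumour:
        raise ValueError("no tumour clones defined")
    supporters = set(event.cells)
    clustered = {cell for c in clones for cell in c.cells}
    if not supporters & clustered:
        raise OrphanEventError(
            f"event {event.key()} has no supporters among clustered cells"
        )
    presence = {}
    for c in tumour:
        covered = sum(1 for cell in c.cells if cell in supporters)
        presence[c.clone_id] = covered >= presence_fraction * c.size
    clonality = "clonal" if all(presence.values()) else "subclonal"
    n_tumour_cells = sum(c.size for c in tumour)
    freq = (
        sum(1 for c in tumour for cell in c.cells if cell in supporters)
        / n_tumour_cells
    )
    return AnnotatedEvent(
        event=event,
        kind="cnv",
        clonality=clonality,
        epoch="initiation" if clonality == "clonal" else "later",
        clone_presence=presence,
        cell_frequency=freq,
    )


def integrate_mutations(
    genotypes: pd.DataFrame,
    clones: list[Clone],
    dropout: float = 0.2,
) -> list[MutationStatus]:
    """Clone-level mutation status from per-cell presence/absence calls.

    ``genotypes`` is long-form with columns ``cell_id``, ``mutation`` and
    ``call`` in {present, absent, missing}.  A clone is *present* when any
    member cell is positive, *indeterminate* when all member calls are
    missing, *absent* otherwise.  Clonality considers determinate tumour
    clones only: clonal iff every such clone is present.  For each absent
    clone the probability delta**m that dropout alone explains the zeros
    is reported.
    """
    required = {"cell_id", "mutation", "call"}
    if not required.issubset(genotypes.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    clustered = {cell for c in clones for cell in c.cells}
    unknown = set(genotypes["cell_id"]) - clustered
    if unknown:
        raise IdMismatchError(
            f"genotype table refers to unclustered cells, e.g. {sorted(unknown)[:3]}"
        )
    tumour = [c for c in clones if not c.is_normal]
    n_tumour_cells = sum(c.size for c in tumour)
    statuses = []
    for mut, sub in genotypes.groupby("mutation", sort=True):
        calls = dict(zip(sub["cell_id"], sub["call"]))
        clone_status: dict[str, str] = {}
        miss_prob: dict[str, float] = {}
        for c in tumour:
            member_calls = [calls.get(cell, "missing") for cell in c.cells]
            if any(v == "present" for v in member_calls):
                clone_status[c.clone_id] = "present"
            elif all(v == "missing" for v in member_calls):
                clone_status[c.clone_id] = "indeterminate"
            else:
                clone_status[c.clone_id] = "absent"
                miss_prob[c.clone_id] = dropout ** sum(
                    1 for v in member_calls if v != "missing"
                )
        determinate = {
            k: v for k, v in clone_status.items() if v != "indeterminate"
        }
        clonality = (
            "clonal"
            if determinate and all(v == "present" for v in determinate.values())
            else "subclonal"
        )
        positives = sum(
            1 for c in tumour for cell in c.cells if calls.get(cell) == "present"
        )
        statuses.append(
            MutationStatus(
                mutation=str(mut),
                clone_status=clone_status,
                clonality=clonality,
                cell_frequency=positives / n_tumour_cells if n_tumour_cells else 0.0,
                miss_probability=miss_prob,
            )
        )
    return statuses


def annotate_mutation(
    status: MutationStatus, clones: list[Clone]
) -> AnnotatedEvent:
    """Wrap a mutation status as an annotated event with epoch."""
    return AnnotatedEvent(
        event=status,
        kind="mutation",
        clonality=status.clonality,
        epoch="initiation" if status.clonality == "clonal" else "later",
        clone_presence={
            k: v == "present" for k, v in status.clone_status.items()
        },
        cell_frequency=status.cell_frequency,
    )


def load_biomarker_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Validate a biomarker table (marker, subgroup, chrom, start, end)."""
    required = ["marker", "subgroup", "chrom", "start", "end"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise BiomarkerTableError(f"biomarker table missing columns {missing}")
    for i, row in rows.iterrows():
        try:
            s, e = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise BiomarkerTableError(f"row {i}: non-integer interval") from exc
        if s >= e:
            raise BiomarkerTableError(f"row {i}: empty interval {s}..{e}")
    return rows[required].copy()


def annotate_biomarkers(
    annotated: list[AnnotatedEvent],
    subgroup: str,
    biomarker_table: pd.DataFrame,
) -> list[AnnotatedEvent]:
    """Flag events overlapping biomarker loci of the tumour's subgroup.

    Interval overlap is evaluated on bp coordinates for CNV events; for
    mutations the marker name must equal the mutation id.  Events whose
    marker context differs from ``subgroup`` are left unflagged.
    """
    table = load_biomarker_table(biomarker_table)
    for ann in annotated:
        for _, row in table.iterrows():
            if str(row["subgroup"]) != subgroup:
                continue
            if ann.kind == "cnv":
                ev: CNVEvent = ann.event
                if ev.chrom == row["chrom"] and not (
                    ev.end_bp <= int(row["start"]) or ev.start_bp >= int(row["end"])
                ):
                    ann.biomarker = str(row["marker"])
                    ann.subgroup_context = subgroup
                    break
            else:
                if ann.event.mutation == str(row["marker"]):
                    ann.biomarker = str(row["marker"])
                    ann.subgroup_context = subgroup
                    break
    return annotated
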