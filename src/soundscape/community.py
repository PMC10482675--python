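"""Community-data operations: richness, occurrence matrices, checklist merging.

Citizen-science collections do not come as standardized point counts; they
are reduced to pseudo point counts by (1) filtering checklists on protocol
quality and (2) merging every checklist that started during an audio
recording into one presence/absence record.
"""
from __future__ import annotations

import logging
from datetime import timedelta
from typing import Sequence

import numpy as np

from .types import Checklist, OccurrenceMatrix, PointCount, Recording

__all__ = [
    "species_richness",
    "build_occurrence_matrix",
    "filter_checklists",
    "merge_checklists_to_point_count",
    "EmptyPointCountError",
]

log = logging.getLogger(__name__)

MAX_CHECKLIST_DISTANCE_M = 200.0
MAX_CHECKLIST_DURATION_MIN = 30.0  # strict: duration must be < this
ALLOWED_PROTOCOLS = frozenset({"travelling", "stationary"})


class EmptyPointCountError(ValueError):
    """No qualifying checklist started during the recording."""


def species_richness(point_count: PointCount) -> int:
    """Alpha diversity: the number of unique species in one point count."""
    return len(point_count.species)


def build_occurrence_matrix(point_counts: Sequence[PointCount]) -> OccurrenceMatrix:
    """Binary presence/absence matrix over the union of observed species.

    Columns are sorted lexicographically; entry (i, j) is 1 iff species j was
    recorded in point count i, so row sums equal per-point-count richness.
    """
    if not point_counts:
        raise ValueError("no point counts supplied")
    datasets = {pc.dataset_id for pc in point_counts}
    if len(datasets) > 1:
        raise ValueError(f"point counts span multiple datasets: {sorted(datasets)}")
    species = sorted(set().union(*(pc.species for pc in point_counts)))
    col = {s: j for j, s in enumerate(species)}
    values = np.zeros((len(point_counts), len(species)), dtype=np.int8)
    for i, pc in enumerate(point_counts):
        for s in pc.species:
            values[i, col[s]] = 1
    return OccurrenceMatrix(
        tuple(pc.id for pc in point_counts), tuple(species), values
    )


def filter_checklists(checklists: Sequence[Checklist]) -> list[Checklist]:
    """Keep checklists suitable for pseudo point counts.

    A checklist survives iff it is complete, of the travelling or stationary
    protocol, within 200 m of the recorder (inclusive) and shorter than
    30 minutes (strict). Idempotent by construction.
    """
    kept = [
        c
        for c in checklists
        if c.complete
        and c.protocol in ALLOWED_PROTOCOLS
        and c.distance_to_recorder <= MAX_CHECKLIST_DISTANCE_M
        and c.duration < MAX_CHECKLIST_DURATION_MIN
    ]
    log.info("filter_checklists: kept %d of %d", len(kept), len(checklists))
    return kept


def merge_checklists_to_point_count(
    recording: Recording, checklists: Sequence[Checklist]
) -> PointCount:
    """Merge checklists that started during a recording into a pseudo point count.

    Membership uses the half-open interval [start, start + duration); the
    species set is the union over matched checklists (occurrence only, so
    double counting is moot). Raises :class:`EmptyPointCountError` when no
    checklist qualifies — callers drop such recordings.
    """
    start = recording.start_time
    end = start + timedelta(seconds=recording.duration)
    matched = [c for c in checklists if start <= c.start_time < end]
    if not matched:
        raise EmptyPointCountError(
            f"no checklist started during recording {recording.id}"
        )
    species = frozenset().union(*(c.species for c in matched))
    return PointCount(
        id=recording.id,
        dataset_id=recording.dataset_id,
        site_id=recording.site_id,
        start_time=start,
        duration=recording.duration / 60.0,
        species=species,
    )
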