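"""Partition query chromosomes into reference-painted segments.

A translocation relative to the reference shows up as a query chromosome
whose shared markers fall on more than one reference chromosome.  Maximal
runs of consecutive markers sharing a reference chromosome become
*segments* (suffix letters a, b, c ... assigned top-to-bottom on the query
map); each junction between two segments is a translocation breakpoint,
bounded by the two adjacent shared markers that disagree about their
reference chromosome.

Runs shorter than ``min_run`` markers are flagged "stray" and excluded
from segments and events: a single out-of-place marker is treated as
potential mapping noise rather than a translocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .map_model_io import ProjectedMarker, ReferenceProjection

logger = logging.getLogger(__name__)

DEFAULT_MIN_RUN = 2

_SUFFIXES = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class BreakpointRegion:
    """Open interval between two adjacent shared markers flanking a junction.

    ``left_rank < right_rank`` on the named reference chromosome; the
    junction lies strictly between the two flanking markers.
    """

    ref_chromosome: str
    left_marker: str
    right_marker: str
    left_rank: int
    right_rank: int

    def __post_init__(self) -> None:
        if self.left_rank >= self.right_rank:
            raise ValueError(
                f"breakpoint on {self.ref_chromosome}: left rank {self.left_rank} "
                f"not below right rank {self.right_rank}"
            )

    def intersection(self, other: "BreakpointRegion") -> tuple[int, int] | None:
        """Narrowed rank interval shared with ``other``, or None if disjoint."""
        if self.ref_chromosome != other.ref_chromosome:
            return None
        lo = max(self.left_rank, other.left_rank)
        hi = min(self.right_rank, other.right_rank)
        return (lo, hi) if lo < hi else None


@dataclass
class ChromosomeSegment:
    """A maximal run of query markers painted by one reference chromosome."""

    segment_id: str
    query_chromosome: str
    ref_chromosome: str
    markers: list[ProjectedMarker]
    species_id: str
    ref_chromosome_size: int | None = None

    @property
    def first_marker(self) -> str:
        return self.markers[0].query_marker

    @property
    def last_marker(self) -> str:
        return self.markers[-1].query_marker

    @property
    def rank_span(self) -> tuple[int, int]:
        ranks = [m.ref_rank for m in self.markers]
        return min(ranks), max(ranks)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class TranslocationEvent:
    """One junction between two reference-painted segments on a query map.

    ``breakpoints`` carries the junction expressed on each of the two
    reference chromosomes involved (where resolvable).  ``embedded`` marks
    the middle segment of an X/Y/X pattern: the Y segment was excised from
    its own chromosome and inserted, the X flanks staying together; the
    two junctions of such a pattern are one biological event.
    """

    species_id: str
    query_chromosome: str
    left_segment: str
    right_segment: str
    query_left_marker: str
    query_right_marker: str
    breakpoints: list[BreakpointRegion] = field(default_factory=list)
    embedded: bool = False
    embedded_segment: str | None = None
    kind: str = "unclassified"

    @property
    def ref_chromosomes(self) -> list[str]:
        return sorted({bp.ref_chromosome for bp in self.breakpoints})


@dataclass
class SegmentPartition:
    species_id: str
    chromosome: str
    segments: list[ChromosomeSegment]
    translocations: list[TranslocationEvent]
    stray_markers: list[ProjectedMarker]


def partition_segments(
    projection: ReferenceProjection, min_run: int = DEFAULT_MIN_RUN
) -> SegmentPartition:
    """Split one projected query chromosome into segments and junctions.

    Returns the partition; segments carry suffix letters in query-map
    order (``E4a``, ``E4b``...) only when the chromosome breaks into more
    than one segment.  A chromosome whose runs are all stray yields zero
    segments and a logged warning.
    """
    if projection.uninformative:
        return SegmentPartition(
            projection.species_id, projection.chromosome, [], [], []
        )

    runs: list[list[ProjectedMarker]] = []
    for marker in projection.markers:
        if runs and runs[-1][-1].ref_chromosome == marker.ref_chromosome:
            runs[-1].append(marker)
        else:
            runs.append([marker])

    # Stray filtering can split a long run in two; re-merge after dropping.
    stray = [m for run in runs if len(run) < min_run for m in run]
    kept = [run for run in runs if len(run) >= min_run]
    merged: list[list[ProjectedMarker]] = []
    for run in kept:
        if merged and merged[-1][-1].ref_chromosome == run[0].ref_chromosome:
            merged[-1].extend(run)
        else:
            merged.append(list(run))

    if not merged:
        logger.warning(
            "%s %s: all %d shared markers stray (runs < %d); no segments",
            projection.species_id, projection.chromosome,
            len(projection.markers), min_run,
        )
        return SegmentPartition(
            projection.species_id, projection.chromosome, [], [], stray
        )

    segments = []
    for i, run in enumerate(merged):
        suffix = _SUFFIXES[i] if len(merged) > 1 else ""
        segments.append(
            ChromosomeSegment(
                segment_id=f"{projection.chromosome}{suffix}",
                query_chromosome=projection.chromosome,
                ref_chromosome=run[0].ref_chromosome,
                markers=run,
                species_id=projection.species_id,
                ref_chromosome_size=projection.ref_sizes.get(run[0].ref_chromosome),
            )
        )

    translocations = []
    for left, right in zip(segments, segments[1:]):
        translocations.append(
            TranslocationEvent(
                species_id=projection.species_id,
                query_chromosome=projection.chromosome,
                left_segment=left.segment_id,
                right_segment=right.segment_id,
                query_left_marker=left.last_marker,
                query_right_marker=right.first_marker,
                breakpoints=_junction_breakpoints(left, right),
            )
        )

    part = SegmentPartition(
        projection.species_id, projection.chromosome, segments, translocations, stray
    )
    detect_embedded_insertion(part)
    return part


def _junction_breakpoints(
    left: ChromosomeSegment, right: ChromosomeSegment
) -> list[BreakpointRegion]:
    """Express one junction on each reference chromosome it breaks.

    On each side, the breakpoint lies between the boundary marker's
    reference rank and the adjacent rank in the direction pointing *out*
    of the segment (away from the segment's interior).
    """
    out = []
    for segment, boundary in ((left, left.markers[-1]), (right, right.markers[0])):
        lo, hi = segment.rank_span
        rank = boundary.ref_rank
        if len(segment) == 1 or rank == hi == lo:
            # direction unresolvable from a single marker; widen both ways
            l, r = rank - 1, rank + 1
        elif rank == hi:
            l, r = rank, rank + 1
        elif rank == lo:
            l, r = rank - 1, rank
        else:
            # boundary marker interior to the segment's rank span (the
            # segment is itself scrambled by inversions); junction rank
            # direction is unresolvable -- use the span edge closest to it.
            l, r = (rank, rank + 1) if hi - rank <= rank - lo else (rank - 1, rank)
        l = max(l, 0)
        out.append(
            BreakpointRegion(
                ref_chromosome=segment.ref_chromosome,
                left_marker=boundary.ref_marker,
                right_marker=boundary.ref_marker,
                left_rank=l,
                right_rank=r,
            )
        )
    return out


def detect_embedded_insertion(partition: SegmentPartition) -> None:
    """Flag X / Y / X patterns as insertional translocations (in place).

    The middle (Y) segment is marked embedded when the two flanking X
    segments are rank-contiguous on the reference: no shared X marker of
    this chromosome falls between their rank spans, so the X material was
    never broken apart -- the Y segment was excised elsewhere and inserted.
    Both junctions of the pattern then describe a single event.
    """
    segs = partition.segments
    for i in range(len(segs) - 2):
        a, b, c = segs[i], segs[i + 1], segs[i + 2]
        if a.ref_chromosome != c.ref_chromosome or a.ref_chromosome == b.ref_chromosome:
            continue
        span_a, span_c = a.rank_span, c.rank_span
        lo, hi = sorted([span_a, span_c])
        if lo[1] >= hi[0]:
            continue  # overlapping spans: not a clean excision flank pair
        between = [
            m
            for seg in segs
            if seg.ref_chromosome == a.ref_chromosome and seg not in (a, c)
            for m in seg.markers
            if lo[1] < m.ref_rank < hi[0]
        ]
        if between:
            continue
        for ev in partition.translocations:
            if {ev.left_segment, ev.right_segment} & {b.segment_id}:
                ev.embedded = True
                ev.embedded_segment = b.segment_id
                ev.kind = "insertional"


def count_junction_events(partition: SegmentPartition) -> int:
    """Number of distinct translocation events on one query chromosome.

    An embedded insertion contributes its two junctions as one event.
    """
    n = 0
    seen_embedded: set[str] = set()
    for ev in partition.translocations:
        if ev.embedded and ev.embedded_segment is not None:
            if ev.embedded_segment in seen_embedded:
                continue
            seen_embedded.add(ev.embedded_segment)
        n += 1
    return n
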