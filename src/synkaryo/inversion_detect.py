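"""Detect inverted blocks within a reference-painted segment.

Inversions are read off the sequence of reference ranks of a segment's
shared markers, in query-map order.  A maximal strictly decreasing run of
ranks is one inverted block; reversing it and iterating peels nested
flips.  When the remaining order cannot be reduced to single flips the
region gets one event carrying a lower bound ``min_count`` (reported with
a "k+" annotation) instead of a fabricated scenario: with sparse markers
the exact number of stacked inversions is not knowable.

Two-marker flips are reported but flagged ``uncertain`` -- a two-marker
swap is indistinguishable from local mapping error; three or more markers
make a ``confident`` call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .map_model_io import CentromereTable, GeneticMap, ProjectedMarker
from .segmentation import BreakpointRegion, ChromosomeSegment

CONFIDENT = "confident"
UNCERTAIN = "uncertain"

PERICENTRIC = "pericentric"
PARACENTRIC = "paracentric"
UNCLASSIFIED = "unclassified"

DEFAULT_MIN_BLOCK = 2
CONFIDENT_MIN_BLOCK = 3


@dataclass
class InversionEvent:
    """One inverted block of a segment, relative to reference rank order."""

    species_id: str
    segment_id: str
    ref_chromosome: str
    block_markers: list[str]  # reference marker ids, query-map order
    rank_span: tuple[int, int]
    breakpoint_low: BreakpointRegion
    breakpoint_high: BreakpointRegion
    min_count: int = 1
    confidence: str = CONFIDENT
    pericentric: str = UNCLASSIFIED
    # positions of the block within the segment at detection time; kept so
    # the detected scenario can be replayed exactly (see replay_events)
    positions: tuple[int, int] = (0, 0)

    @property
    def annotation(self) -> str:
        return f"{self.min_count}+" if self.min_count > 1 else "1"

    @property
    def exact(self) -> bool:
        return self.min_count == 1


def detect_inversions(
    segment: ChromosomeSegment,
    min_block: int = DEFAULT_MIN_BLOCK,
    max_rounds: int | None = None,
) -> list[InversionEvent]:
    """Decompose a segment's rank sequence into inversion events.

    Events are returned in inferred historical order: applying them first
    to last to the reference order reproduces the observed segment order
    (exact events only; ``min_count > 1`` events are unresolved bounds).
    Segments with fewer than three shared markers are uninformative and
    yield no events.
    """
    markers = segment.markers
    if len(markers) < 3:
        return []

    ranks = [m.ref_rank for m in markers]
    sorted_ranks = sorted(ranks)
    rank_index = {r: i for i, r in enumerate(sorted_ranks)}  # rank -> shared index
    seq = list(ranks)
    if max_rounds is None:
        max_rounds = len(seq) + 4

    recorded: list[tuple[int, int, list[int]]] = []  # (i, j, block ranks)
    for _ in range(max_rounds):
        if _is_sorted(seq):
            break
        # candidate flips: maximal strictly decreasing runs whose ranks are
        # contiguous in the shared-marker set -- the signature of one real
        # inversion; anything else is left for the lower-bound fallback
        # rather than being explained by an invented scenario
        runs = [
            (i, j)
            for i, j in _decreasing_runs(seq, min_len=2)
            if rank_index[seq[j]] + (j - i) == rank_index[seq[i]]
        ]
        if not runs:
            break
        before = _breakpoint_count(seq, rank_index)
        i, j = max(runs, key=lambda r: r[1] - r[0])
        candidate = seq[:i] + seq[i : j + 1][::-1] + seq[j + 1 :]
        if _breakpoint_count(candidate, rank_index) >= before:
            break  # reversal does not simplify the order
        recorded.append((i, j, seq[i : j + 1]))
        seq = candidate

    events: list[InversionEvent] = []
    # detection walked observed -> reference; historical order is the reverse
    for i, j, block in reversed(recorded):
        if len(block) < min_block:
            continue
        events.append(
            _make_event(segment, block, rank_index, sorted_ranks, positions=(i, j))
        )

    if not _is_sorted(seq):
        events.extend(
            _irreducible_events(segment, seq, rank_index, sorted_ranks)
        )
    return events


def replay_events(segment: ChromosomeSegment, events: list[InversionEvent]) -> list[int]:
    """Apply exact detected events (first to last) to the reference order.

    Returns the resulting rank sequence; equals the observed segment rank
    sequence whenever every event is exact (``min_count == 1``).
    """
    seq = sorted(m.ref_rank for m in segment.markers)
    for ev in events:
        i, j = ev.positions
        seq = seq[:i] + seq[i : j + 1][::-1] + seq[j + 1 :]
    return seq


def classify_pericentric(
    event: InversionEvent,
    centromeres: CentromereTable,
    reference: GeneticMap | None = None,
    flank_ranks: tuple[int, int] | None = None,
) -> str:
    """Set and return the pericentric/paracentric flag of an event.

    Pericentric iff the block's reference rank interval contains the
    centromere's flanking-marker interval.  The centromere interval comes
    either from ``flank_ranks`` directly or is resolved against the
    reference map.  Unknown centromere -> ``unclassified``.
    """
    chrom = event.ref_chromosome
    if flank_ranks is None:
        if chrom not in centromeres or reference is None:
            event.pericentric = UNCLASSIFIED
            return event.pericentric
        flank_ranks = centromeres.flank_ranks(chrom, reference)
    lo, hi = event.rank_span
    cl, cr = flank_ranks
    event.pericentric = PERICENTRIC if lo <= cl and hi >= cr else PARACENTRIC
    return event.pericentric


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _is_sorted(seq: list[int]) -> bool:
    return all(a < b for a, b in zip(seq, seq[1:]))


def _decreasing_runs(seq: list[int], min_len: int) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for k in range(1, len(seq) + 1):
        if k == len(seq) or seq[k] >= seq[k - 1]:
            if k - start >= min_len:
                runs.append((start, k - 1))
            start = k
    return runs


def _breakpoint_count(seq: list[int], rank_index: dict[int, int]) -> int:
    """Broken adjacencies, with virtual frame markers at both ends."""
    idx = [rank_index[r] for r in seq]
    framed = [-1] + idx + [len(idx)]
    return sum(1 for a, b in zip(framed, framed[1:]) if abs(a - b) != 1)


def _flanking_breakpoints(
    segment: ChromosomeSegment,
    block_ranks: list[int],
    sorted_ranks: list[int],
) -> tuple[BreakpointRegion, BreakpointRegion]:
    """Breakpoint intervals between the block's rank extremes and the
    nearest shared markers outside the block (or the segment edge)."""
    marker_of = {m.ref_rank: m.ref_marker for m in segment.markers}
    lo, hi = min(block_ranks), max(block_ranks)
    lo_i, hi_i = sorted_ranks.index(lo), sorted_ranks.index(hi)
    # with no shared marker beyond the block the junction is bounded only
    # by the chromosome end (ranks outside the shared set may be unmapped)
    below = sorted_ranks[lo_i - 1] if lo_i > 0 else 0
    if hi_i + 1 < len(sorted_ranks):
        above = sorted_ranks[hi_i + 1]
    elif segment.ref_chromosome_size is not None:
        above = max(segment.ref_chromosome_size, hi) + 1
    else:
        above = hi + 1
    bp_low = BreakpointRegion(
        ref_chromosome=segment.ref_chromosome,
        left_marker=marker_of.get(below, "-"),
        right_marker=marker_of[lo],
        left_rank=below,
        right_rank=lo,
    )
    bp_high = BreakpointRegion(
        ref_chromosome=segment.ref_chromosome,
        left_marker=marker_of[hi],
        right_marker=marker_of.get(above, "-"),
        left_rank=hi,
        right_rank=above,
    )
    return bp_low, bp_high


def _make_event(
    segment: ChromosomeSegment,
    block_ranks: list[int],
    rank_index: dict[int, int],
    sorted_ranks: list[int],
    positions: tuple[int, int],
    min_count: int = 1,
) -> InversionEvent:
    marker_of = {m.ref_rank: m.ref_marker for m in segment.markers}
    bp_low, bp_high = _flanking_breakpoints(segment, block_ranks, sorted_ranks)
    confident = len(block_ranks) >= CONFIDENT_MIN_BLOCK
    return InversionEvent(
        species_id=segment.species_id,
        segment_id=segment.segment_id,
        ref_chromosome=segment.ref_chromosome,
        block_markers=[marker_of[r] for r in block_ranks],
        rank_span=(min(block_ranks), max(block_ranks)),
        breakpoint_low=bp_low,
        breakpoint_high=bp_high,
        min_count=min_count,
        confidence=CONFIDENT if confident else UNCERTAIN,
        positions=positions,
    )


def _irreducible_events(
    segment: ChromosomeSegment,
    seq: list[int],
    rank_index: dict[int, int],
    sorted_ranks: list[int],
) -> list[InversionEvent]:
    """One lower-bound ("k+") event per maximal out-of-order region."""
    n = len(seq)
    idx = [rank_index[r] for r in seq]
    # sorted-block decomposition: a boundary falls after position k when
    # the prefix holds exactly the k+1 smallest shared indices; maximal
    # non-singleton blocks are the scrambled regions
    regions: list[tuple[int, int]] = []
    start = 0
    running_max = -1
    for k in range(n):
        running_max = max(running_max, idx[k])
        if running_max == k:
            if k > start:
                regions.append((start, k))
            start = k + 1

    events = []
    for i, j in regions:
        sub = seq[i : j + 1]
        local_index = {r: k for k, r in enumerate(sorted(sub))}
        b = _breakpoint_count(sub, local_index)
        min_count = max(1, math.ceil(b / 2))
        events.append(
            _make_event(
                segment, sub, rank_index, sorted_ranks,
                positions=(i, j), min_count=min_count,
            )
        )
    return events
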