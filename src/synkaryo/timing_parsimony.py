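"""Place rearrangement events on branches of a dated phylogeny by parsimony.

Every event is observed as a *pattern* over species: relative to the
common reference map each species either shares the reference order (R),
carries the event (E), or is uninformative (U) for the region -- e.g.
because a translocation reshuffled it or too few markers were mapped.

Two-state parsimony on the fixed topology then reduces to a split search:
the event happened on a branch whose removal separates the R species from
the E species.  Exactly one such branch -> the assignment is determined
(note the reference species is not privileged: a pattern where everything
*but* the reference carries the event assigns the event to the reference's
own terminal branch).  Several consistent branches -> an explicit
candidate set; none -> the carriers arose by independent events and each
carrier clade is assigned separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .map_model_io import Phylogeny
from .segmentation import BreakpointRegion

INVERSION = "inversion"
TRANSLOCATION = "translocation"

REF_ORDER = "R"
HAS_EVENT = "E"
UNINFORMATIVE = "U"

# comparison verdicts (pairwise, via the reference)
SAME_ORDER = "same_order"
SHARED_EVENT = "shared_event"
INDEPENDENT_EVENTS = "independent_events"
POSSIBLY_SHARED = "possibly_shared"

# assignment rationales
SHARED_DERIVED = "shared_derived"
REFERENCE_DERIVED = "reference_derived"
INDEPENDENT = "independent"
OUTGROUP_UNINFORMATIVE = "outgroup_uninformative"

OBSERVATION_FIXED_COLUMNS = [
    "event_id", "kind", "ref_chromosome", "span_lo", "span_hi", "min_count",
]


class NotComparableError(ValueError):
    """Two events do not reference the same chromosome/region."""


@dataclass
class EventObservation:
    """One rearrangement event and its presence pattern across species."""

    event_id: str
    kind: str  # inversion | translocation
    ref_chromosome: str
    span: tuple[int, int]  # block rank span (inversion) / breakpoint interval
    states: dict[str, str]  # species -> R | E | U
    min_count: int = 1
    source: str = "detected"
    note: str = ""
    bp_low: tuple[int, int] | None = None
    bp_high: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.states.values()} - {REF_ORDER, HAS_EVENT, UNINFORMATIVE}
        if bad:
            raise ValueError(f"{self.event_id}: bad state codes {sorted(bad)}")
        if HAS_EVENT not in self.states.values():
            raise ValueError(f"{self.event_id}: no species carries the event")

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(s for s, st in self.states.items() if st == HAS_EVENT)

    @property
    def sharers(self) -> frozenset[str]:
        return frozenset(s for s, st in self.states.items() if st == REF_ORDER)


@dataclass
class LineageAssignment:
    """Branch placement (or candidate branch set) for one event."""

    event_id: str
    kind: str
    ref_chromosome: str
    branch: str | None  # set iff determined
    candidate_set: frozenset[str]
    rationale: str
    min_count: int = 1
    carriers: frozenset[str] = frozenset()

    @property
    def determined(self) -> bool:
        return self.branch is not None


@dataclass
class Comparison:
    verdict: str
    narrowed: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Figure-style pairwise comparison via the reference
# ---------------------------------------------------------------------------


def _intersect(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo < hi else None


def compare_inversions(
    span_a: tuple[int, int],
    bp_a: tuple[tuple[int, int], tuple[int, int]],
    span_b: tuple[int, int],
    bp_b: tuple[tuple[int, int], tuple[int, int]],
) -> Comparison:
    """Compare two species-vs-reference inversions on one reference region.

    Shared iff the inverted blocks overlap and *both* breakpoint flanking
    intervals overlap: an inverted region seen in two species is the same
    event only when neither end can be told apart at marker resolution.
    Overlapping blocks whose ends differ must be two independent events.
    """
    spans_overlap = span_a[0] <= span_b[1] and span_b[0] <= span_a[1]
    low = _intersect(bp_a[0], bp_b[0])
    high = _intersect(bp_a[1], bp_b[1])
    if spans_overlap and low is not None and high is not None:
        return Comparison(SHARED_EVENT)
    return Comparison(INDEPENDENT_EVENTS)


def compare_translocations(
    interval_a: tuple[int, int], interval_b: tuple[int, int]
) -> Comparison:
    """Translocation junctions sharing any part of their breakpoint interval
    possibly share the breakpoint; the region narrows to the overlap."""
    narrowed = _intersect(interval_a, interval_b)
    if narrowed is not None:
        return Comparison(POSSIBLY_SHARED, narrowed)
    return Comparison(INDEPENDENT_EVENTS)


def compare_via_reference(ev_a, ev_b) -> Comparison:
    """Dispatch on event kind; events must share a reference chromosome.

    Accepts :class:`EventObservation`, detected inversion events (with
    ``breakpoint_low/high`` and ``rank_span``), or translocation
    breakpoint regions.
    """
    chrom_a, chrom_b = _ref_chrom(ev_a), _ref_chrom(ev_b)
    if chrom_a != chrom_b:
        raise NotComparableError(
            f"events on different reference chromosomes: {chrom_a} vs {chrom_b}"
        )
    kind_a, kind_b = _kind(ev_a), _kind(ev_b)
    if kind_a != kind_b:
        raise NotComparableError(f"cannot compare {kind_a} with {kind_b}")
    if kind_a == INVERSION:
        return compare_inversions(
            _span(ev_a), _bps(ev_a), _span(ev_b), _bps(ev_b)
        )
    return compare_translocations(_interval(ev_a), _interval(ev_b))


def _ref_chrom(ev) -> str:
    return getattr(ev, "ref_chromosome")


def _kind(ev) -> str:
    kind = getattr(ev, "kind", None)
    if kind in (INVERSION, TRANSLOCATION):
        return kind
    if hasattr(ev, "breakpoint_low") or hasattr(ev, "block_markers"):
        return INVERSION
    return TRANSLOCATION


def _span(ev) -> tuple[int, int]:
    return tuple(getattr(ev, "rank_span", None) or getattr(ev, "span"))


def _bps(ev) -> tuple[tuple[int, int], tuple[int, int]]:
    bp_low = getattr(ev, "breakpoint_low", None)
    bp_high = getattr(ev, "breakpoint_high", None)
    if isinstance(bp_low, BreakpointRegion):
        bp_low = (bp_low.left_rank, bp_low.right_rank)
        bp_high = (bp_high.left_rank, bp_high.right_rank)
    if bp_low is None:
        bp_low = getattr(ev, "bp_low", None)
        bp_high = getattr(ev, "bp_high", None)
    if bp_low is None:
        lo, hi = _span(ev)
        bp_low, bp_high = (lo - 1, lo), (hi, hi + 1)
    return tuple(bp_low), tuple(bp_high)


def _interval(ev) -> tuple[int, int]:
    if isinstance(ev, BreakpointRegion):
        return (ev.left_rank, ev.right_rank)
    if hasattr(ev, "span"):
        return tuple(ev.span)
    bps = getattr(ev, "breakpoints", None)
    if bps:
        return (bps[0].left_rank, bps[0].right_rank)
    raise NotComparableError("no breakpoint interval on event")


# ---------------------------------------------------------------------------
# Branch assignment
# ---------------------------------------------------------------------------


def _separating_branches(
    tree: Phylogeny, sharers: frozenset[str], carriers: frozenset[str]
) -> list[str]:
    """Branches whose split puts all sharers on one side, all carriers on
    the other (uninformative tips fall wherever they fall)."""
    all_tips = frozenset(tree.tips)
    out = []
    for branch in tree.branches:
        below = tree.tipset(branch)
        above = all_tips - below
        if (carriers <= below and sharers <= above) or (
            sharers <= below and carriers <= above
        ):
            out.append(branch)
    return out


def assign_lineage(
    obs: EventObservation, tree: Phylogeny, reference: str
) -> list[LineageAssignment]:
    """Assign one event to a branch, a candidate set, or split it up.

    The reference species is treated like any other sharer (its map *is*
    the reference order), so a pattern carried by every non-reference
    species lands on the reference terminal branch.  Returns one
    assignment normally; several (rationale ``independent``) when the
    carriers cannot descend from a single event.
    """
    states = dict(obs.states)
    states.setdefault(reference, REF_ORDER)
    missing = set(tree.tips) - set(states)
    if missing:
        raise ValueError(f"{obs.event_id}: no state for species {sorted(missing)}")

    sharers = frozenset(s for s, st in states.items() if st == REF_ORDER)
    carriers = frozenset(s for s, st in states.items() if st == HAS_EVENT)
    return _assign(obs, tree, sharers, carriers, rationale_override=None)


def _assign(
    obs: EventObservation,
    tree: Phylogeny,
    sharers: frozenset[str],
    carriers: frozenset[str],
    rationale_override: str | None,
) -> list[LineageAssignment]:
    branches = _separating_branches(tree, sharers, carriers)
    if len(branches) == 1:
        branch = branches[0]
        rationale = rationale_override or (
            REFERENCE_DERIVED
            if tree.is_tip(branch) and branch in sharers
            else SHARED_DERIVED
        )
        return [
            LineageAssignment(
                obs.event_id, obs.kind, obs.ref_chromosome,
                branch=branch, candidate_set=frozenset([branch]),
                rationale=rationale, min_count=obs.min_count, carriers=carriers,
            )
        ]
    if len(branches) > 1:
        return [
            LineageAssignment(
                obs.event_id, obs.kind, obs.ref_chromosome,
                branch=None, candidate_set=frozenset(branches),
                rationale=rationale_override or OUTGROUP_UNINFORMATIVE,
                min_count=obs.min_count, carriers=carriers,
            )
        ]
    # No single branch separates carriers from sharers: several independent
    # state changes are needed.  Two-state parsimony is symmetric, so the
    # minimal scenario may cut around either the carriers (the event arose
    # several times) or the sharers (the event is older and the reference
    # order re-arose); take whichever needs fewer changes, carriers on ties.
    carrier_side = _carrier_clades(tree, sharers, carriers)
    sharer_side = _carrier_clades(tree, carriers, sharers)
    if len(sharer_side) < len(carrier_side):
        clades, opposite = sharer_side, carriers
    else:
        clades, opposite = carrier_side, sharers
    out: list[LineageAssignment] = []
    for clade in clades:
        out.extend(
            _assign(obs, tree, opposite, clade, rationale_override=INDEPENDENT)
        )
    return out


def _carrier_clades(
    tree: Phylogeny, sharers: frozenset[str], carriers: frozenset[str]
) -> list[frozenset[str]]:
    """Partition carriers into maximal sharer-free groups.

    Groups live on the unrooted tree: each side of each edge (including
    the side containing the root) is a candidate, so e.g. two carriers
    flanking the root can still be one event."""
    all_tips = frozenset(tree.tips)
    sides = [tree.tipset(b) for b in tree.branches]
    sides += [all_tips - s for s in sides]
    sides.sort(key=len, reverse=True)
    taken: set[str] = set()
    clades: list[frozenset[str]] = []
    for side in sides:
        if side & sharers or not side & carriers:
            continue
        if side & taken:
            continue
        clades.append(frozenset(side & carriers))
        taken |= side
    return clades


# ---------------------------------------------------------------------------
# Per-branch counting
# ---------------------------------------------------------------------------


@dataclass
class BranchCount:
    branch: str
    kind: str
    determined: int = 0
    undetermined_max: int = 0  # undetermined events whose candidate set has branch

    @property
    def count_min(self) -> int:
        return self.determined

    @property
    def count_max(self) -> int:
        return self.determined + self.undetermined_max


@dataclass
class CountTable:
    counts: dict[tuple[str, str], BranchCount] = field(default_factory=dict)
    undetermined: dict[str, list[LineageAssignment]] = field(default_factory=dict)

    def get(self, branch: str, kind: str) -> BranchCount:
        return self.counts.setdefault(
            (branch, kind), BranchCount(branch=branch, kind=kind)
        )

    def n_undetermined(self, kind: str, candidate_set: Iterable[str] | None = None) -> int:
        wanted = None if candidate_set is None else frozenset(candidate_set)
        n = 0
        for a in self.undetermined.get(kind, []):
            if wanted is None or a.candidate_set == wanted:
                n += a.min_count
        return n


def count_events_by_branch(
    assignments: Iterable[LineageAssignment], tree: Phylogeny
) -> CountTable:
    """Tally determined counts per branch and undetermined min/max ranges.

    Undetermined events contribute to ``count_max`` of every branch in
    their candidate set and to ``count_min`` of none; events with a
    ``min_count`` lower bound contribute that many.
    """
    table = CountTable()
    for branch in tree.branches:
        for kind in (INVERSION, TRANSLOCATION):
            table.get(branch, kind)
    for a in assignments:
        if a.determined:
            table.get(a.branch, a.kind).determined += a.min_count
        else:
            table.undetermined.setdefault(a.kind, []).append(a)
            for branch in a.candidate_set:
                table.get(branch, a.kind).undetermined_max += a.min_count
    return table


# ---------------------------------------------------------------------------
# Observation table I/O
# ---------------------------------------------------------------------------


def load_observations(path: str | Path) -> list[EventObservation]:
    """Read an observation TSV: fixed columns, then one state column per
    species, then a trailing free-text ``note`` column."""
    path = Path(path)
    out: list[EventObservation] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [h.strip() for h in row]
                if header[: len(OBSERVATION_FIXED_COLUMNS)] != OBSERVATION_FIXED_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: bad observation header")
                species_cols = header[len(OBSERVATION_FIXED_COLUMNS) : -1]
                continue
            rec = dict(zip(header, (f.strip() for f in row)))
            out.append(
                EventObservation(
                    event_id=rec["event_id"],
                    kind=rec["kind"],
                    ref_chromosome=rec["ref_chromosome"],
                    span=(int(rec["span_lo"]), int(rec["span_hi"])),
                    min_count=int(rec["min_count"]),
                    states={sp: rec[sp] for sp in species_cols},
                    source="fixture",
                    note=rec.get("note", ""),
                )
            )
    if header is None:
        raise ValueError(f"{path}: empty observation file")
    return out


def write_assignments(
    assignments: Iterable[LineageAssignment], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["event_id", "kind", "ref_chromosome", "branch", "candidate_set",
             "rationale", "min_count"]
        )
        for a in assignments:
            writer.writerow(
                [
                    a.event_id, a.kind, a.ref_chromosome,
                    a.branch or "",
                    ";".join(sorted(a.candidate_set)),
                    a.rationale, a.min_count,
                ]
            )
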