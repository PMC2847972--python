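"""End-to-end comparative analysis and its truth-evaluation harness.

``run_comparative_analysis`` drives the whole chain on a set of maps: each
non-reference species is projected onto the reference, segmented and
scanned for inversions; per-species detections are merged across species
into event observations (shared iff breakpoint intervals agree, per the
reference-mediated comparison rules); observations are placed on the tree
by parsimony; ancestral arrangements are reconstructed marker-by-marker.

``evaluate_against_truth`` scores a run against a simulator history:
recall of observable events, breakpoint-interval containment, branch
assignment accuracy for events with an informative outgroup, and
ancestral-arrangement correctness on resolved chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .inversion_detect import InversionEvent, detect_inversions
from .map_model_io import GeneticMap, OrthologyTable, Phylogeny, project_onto_reference
from .segmentation import SegmentPartition, partition_segments
from .synthetic_data import TrueEvent, TrueHistory
from .timing_parsimony import (
    HAS_EVENT,
    INVERSION,
    REF_ORDER,
    SHARED_EVENT,
    TRANSLOCATION,
    UNINFORMATIVE,
    EventObservation,
    LineageAssignment,
    assign_lineage,
    compare_via_reference,
    count_events_by_branch,
)

MIN_INFORMATIVE_MARKERS = 3


@dataclass
class SpeciesDetection:
    species: str
    partitions: dict[str, SegmentPartition]  # query chromosome -> partition
    inversions: list[InversionEvent]

    def segments_on(self, ref_chromosome: str):
        for part in self.partitions.values():
            for seg in part.segments:
                if seg.ref_chromosome == ref_chromosome:
                    yield seg


@dataclass
class AnalysisResult:
    reference: str
    detections: dict[str, SpeciesDetection]
    observations: list[EventObservation]
    assignments: list[LineageAssignment]
    ancestors: dict[str, "AncestralArrangement"]
    cluster_members: dict[str, list[InversionEvent]] = field(default_factory=dict)

    def count_table(self, tree: Phylogeny):
        return count_events_by_branch(self.assignments, tree)


def detect_species(
    query: GeneticMap,
    reference: GeneticMap,
    orthology: OrthologyTable,
    min_run: int = 2,
    min_block: int = 2,
) -> SpeciesDetection:
    projections = project_onto_reference(query, reference, orthology)
    partitions = {}
    inversions = []
    for chrom, projection in projections.items():
        part = partition_segments(projection, min_run=min_run)
        partitions[chrom] = part
        for segment in part.segments:
            inversions.extend(detect_inversions(segment, min_block=min_block))
    return SpeciesDetection(query.species_id, partitions, inversions)


# ---------------------------------------------------------------------------
# Cross-species merging of detections into observations
# ---------------------------------------------------------------------------


def _merge_inversions(
    detections: dict[str, SpeciesDetection]
) -> list[list[InversionEvent]]:
    """Cluster per-species inversions that share both breakpoint intervals.

    Coinciding breakpoint intervals alone can be chance (independent
    events in a reused region), so a pair is merged only if the inverted
    blocks also contain the same markers wherever both species mapped a
    marker -- one same-region marker inside one block but outside the
    other refutes identity.
    """
    events = [ev for det in detections.values() for ev in det.inversions]
    markers_of: dict[str, set[str]] = {
        sp: {
            m.ref_marker
            for part in det.partitions.values()
            for seg in part.segments
            for m in seg.markers
        }
        for sp, det in detections.items()
    }
    parent = list(range(len(events)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            a, b = events[i], events[j]
            if a.ref_chromosome != b.ref_chromosome:
                continue
            if a.species_id == b.species_id:
                continue
            if compare_via_reference(a, b).verdict != SHARED_EVENT:
                continue
            both = markers_of[a.species_id] & markers_of[b.species_id]
            if set(a.block_markers) & both != set(b.block_markers) & both:
                continue
            parent[find(i)] = find(j)

    clusters: dict[int, list[InversionEvent]] = {}
    for i, ev in enumerate(events):
        clusters.setdefault(find(i), []).append(ev)
    return list(clusters.values())


def _region_state(
    detection: SpeciesDetection,
    ref_chromosome: str,
    span: tuple[int, int],
    cluster_species: set[str],
) -> str:
    """R/U call for a species that does not carry a cluster's event.

    A species is informative for a region only when one of its segments
    covers the region's rank span with enough shared markers and no
    translocation junction inside -- a reshuffled or sparsely mapped
    region can neither confirm nor refute the event (the distant-outgroup
    guard).  A species with its own, different event overlapping the
    region is uninformative for this one.
    """
    lo, hi = span
    covering = None
    for seg in detection.segments_on(ref_chromosome):
        s_lo, s_hi = seg.rank_span
        if s_lo <= lo and s_hi >= hi:
            covering = seg
            break
    if covering is None:
        return UNINFORMATIVE
    inside = [m.ref_rank for m in covering.markers if lo <= m.ref_rank <= hi]
    if len(inside) < MIN_INFORMATIVE_MARKERS - 1 or len(covering) < MIN_INFORMATIVE_MARKERS:
        return UNINFORMATIVE
    if inside != sorted(inside):
        return UNINFORMATIVE  # locally scrambled, yet no clean event called
    for ev in detection.inversions:
        if ev.ref_chromosome != ref_chromosome:
            continue
        e_lo, e_hi = ev.rank_span
        if e_lo <= hi and lo <= e_hi:
            return UNINFORMATIVE  # overlapped by a different event of its own
    return REF_ORDER


def build_observations(
    detections: dict[str, SpeciesDetection],
    tree: Phylogeny,
    reference: str,
) -> tuple[list[EventObservation], dict[str, list[InversionEvent]]]:
    """Merge per-species detections into per-event presence patterns."""
    observations: list[EventObservation] = []
    cluster_members: dict[str, list[InversionEvent]] = {}

    for idx, cluster in enumerate(_merge_inversions(detections)):
        lead = min(cluster, key=lambda e: (e.rank_span, e.species_id))
        carriers = {ev.species_id for ev in cluster}
        states: dict[str, str] = {}
        for species in tree.tips:
            if species == reference:
                continue
            if species in carriers:
                states[species] = HAS_EVENT
            else:
                states[species] = _region_state(
                    detections[species], lead.ref_chromosome, lead.rank_span, carriers
                )
        event_id = f"inv_{lead.ref_chromosome}_{idx:03d}"
        obs = EventObservation(
            event_id=event_id,
            kind=INVERSION,
            ref_chromosome=lead.ref_chromosome,
            span=lead.rank_span,
            states=states,
            min_count=max(ev.min_count for ev in cluster),
            bp_low=(lead.breakpoint_low.left_rank, lead.breakpoint_low.right_rank),
            bp_high=(lead.breakpoint_high.left_rank, lead.breakpoint_high.right_rank),
        )
        observations.append(obs)
        cluster_members[event_id] = cluster

    observations.extend(_translocation_observations(detections, tree, reference))
    return observations, cluster_members


def _translocation_observations(
    detections: dict[str, SpeciesDetection],
    tree: Phylogeny,
    reference: str,
) -> list[EventObservation]:
    """One observation per translocation junction, grouped across species
    when junction intervals on the reference intersect."""
    junctions = []  # (species, ref_chrom, interval)
    for det in detections.values():
        seen_embedded = set()
        for part in det.partitions.values():
            for ev in part.translocations:
                if ev.embedded and ev.embedded_segment in seen_embedded:
                    continue
                if ev.embedded:
                    seen_embedded.add(ev.embedded_segment)
                for bp in ev.breakpoints:
                    junctions.append(
                        (det.species, bp.ref_chromosome, (bp.left_rank, bp.right_rank))
                    )

    parent = list(range(len(junctions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(junctions)):
        for j in range(i + 1, len(junctions)):
            sp_a, ch_a, iv_a = junctions[i]
            sp_b, ch_b, iv_b = junctions[j]
            if ch_a != ch_b or sp_a == sp_b:
                continue
            if max(iv_a[0], iv_b[0]) < min(iv_a[1], iv_b[1]):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(junctions)):
        clusters.setdefault(find(i), []).append(i)

    out = []
    for n, members in enumerate(clusters.values()):
        carriers = {junctions[i][0] for i in members}
        chrom = junctions[members[0]][1]
        lo = max(junctions[i][2][0] for i in members)
        hi = min(junctions[i][2][1] for i in members)
        if lo >= hi:
            lo = min(junctions[i][2][0] for i in members)
            hi = max(junctions[i][2][1] for i in members)
        states = {}
        for species in tree.tips:
            if species == reference:
                continue
            if species in carriers:
                states[species] = HAS_EVENT
            else:
                det = detections[species]
                informative = any(
                    seg.rank_span[0] <= lo and seg.rank_span[1] >= hi and len(seg) >= 2
                    for seg in det.segments_on(chrom)
                )
                states[species] = REF_ORDER if informative else UNINFORMATIVE
        out.append(
            EventObservation(
                event_id=f"tr_{chrom}_{n:03d}",
                kind=TRANSLOCATION,
                ref_chromosome=chrom,
                span=(lo, hi),
                states=states,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Marker-level ancestral arrangement reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralArrangement:
    """Per-reference-chromosome arrangement signatures at an internal node.

    ``chrom_markers`` records, per chromosome, the marker set the resolved
    signature is expressed over: the daughters' shared markers when they
    agree, or only the markers the deciding outgroup could actually see
    when polarity came from an outgroup (markers invisible to every
    outgroup cannot be polarised and are not claimed).
    """

    node: str
    signatures: dict[str, frozenset]  # ref chromosome id -> resolved signature
    resolved: set[str] = field(default_factory=set)
    marker_set: set[str] = field(default_factory=set)
    chrom_markers: dict[str, set[str]] = field(default_factory=dict)
    daughter_reps: dict[str, tuple[str, str]] = field(default_factory=dict)


def _signature(
    chromosomes: Iterable[list[str]],
    ref_chrom: str,
    origin: dict[str, str],
    markers: set[str],
) -> frozenset:
    """Canonical arrangement signature of one reference chromosome's
    material inside a genome, restricted to ``markers``.

    Per query chromosome carrying material of ``ref_chrom``: the maximal
    runs of that material (ordered marker tuples) with the origin of the
    neighbouring material at each end.  Canonical under whole-chromosome
    reversal, and assembled into a frozenset so chromosome order is free.
    """
    parts = []
    for chrom in chromosomes:
        seq = [m for m in chrom if m in markers]
        if not any(origin[m] == ref_chrom for m in seq):
            continue
        runs = []
        i = 0
        while i < len(seq):
            if origin[seq[i]] != ref_chrom:
                i += 1
                continue
            j = i
            while j < len(seq) and origin[seq[j]] == ref_chrom:
                j += 1
            left = origin[seq[i - 1]] if i > 0 else None
            right = origin[seq[j]] if j < len(seq) else None
            runs.append((left, tuple(seq[i:j]), right))
            i = j
        fwd = tuple((l or "", t, r or "") for (l, t, r) in runs)
        rev = tuple(
            (r or "", tuple(reversed(t)), l or "") for (l, t, r) in reversed(runs)
        )
        parts.append(min(fwd, rev))
    return frozenset(parts)


def reconstruct_arrangements(
    tree: Phylogeny,
    genomes: dict[str, list[list[str]]],
    marker_sets: dict[str, set[str]],
    origin: dict[str, str],
    reference: str,
    ref_chromosomes: list[str],
) -> dict[str, AncestralArrangement]:
    """Reconstruct internal-node arrangements tipward-first.

    At each node the two daughter lineages are compared per reference
    chromosome; agreement resolves the ancestor.  On disagreement the
    decision goes to the *closest* outgroup that can see the difference
    (the two daughters still differ when restricted to markers that
    outgroup retains): the daughter it matches preserved the ancestral
    arrangement; if it matches neither daughter, the chromosome stays
    unresolved.  The resolved signature is claimed only over markers the
    deciding outgroup could actually vouch for.  A resolved chromosome is
    represented by an extant tip whose genome preserves the node's
    arrangement; parents compare against that tip's genome, restricted to
    the node's shared marker set.  The root is skipped (no outgroup).
    """
    internal = sorted(
        (n for n in tree.branches if not tree.is_tip(n)),
        key=lambda n: tree.node_ages[n],
    )
    out: dict[str, AncestralArrangement] = {}
    node_markers: dict[str, set[str]] = {t: set(marker_sets[t]) for t in tree.tips}
    # per node, per chromosome: the extant tip representing its arrangement
    rep_tip: dict[str, dict[str, str | None]] = {
        t: {c: t for c in ref_chromosomes} for t in tree.tips
    }

    for node in internal:
        d1, d2 = tree.children(node)
        common = node_markers[d1] & node_markers[d2]
        inside = tree.tipset(node)
        anchor = min(inside)
        outgroups = sorted(
            (t for t in tree.tips if t not in inside),
            key=lambda t: tree.node_ages[tree.mrca([t, anchor])],
        )
        signatures: dict[str, frozenset] = {}
        resolved: set[str] = set()
        chrom_markers: dict[str, set[str]] = {}
        reps: dict[str, str | None] = {}
        daughter_reps: dict[str, tuple[str, str]] = {}
        for chrom in ref_chromosomes:
            rep1, rep2 = rep_tip[d1][chrom], rep_tip[d2][chrom]
            if rep1 is None or rep2 is None:
                reps[chrom] = None
                continue
            daughter_reps[chrom] = (rep1, rep2)
            sig1 = _signature(genomes[rep1], chrom, origin, common)
            sig2 = _signature(genomes[rep2], chrom, origin, common)
            if sig1 == sig2:
                signatures[chrom] = sig1
                resolved.add(chrom)
                chrom_markers[chrom] = set(common)
                reps[chrom] = rep1
                continue
            winner: str | None = None
            winner_markers: set[str] | None = None
            for og in outgroups:
                og_common = common & node_markers[og]
                s1 = _signature(genomes[rep1], chrom, origin, og_common)
                s2 = _signature(genomes[rep2], chrom, origin, og_common)
                if s1 == s2:
                    continue  # this outgroup is blind to the difference
                so = _signature(genomes[og], chrom, origin, og_common)
                if so == s1:
                    winner, winner_markers = rep1, set(og_common)
                elif so == s2:
                    winner, winner_markers = rep2, set(og_common)
                # closest sighted outgroup decides; matching neither
                # daughter means no lineage demonstrably preserved the
                # ancestral arrangement -> unresolved
                break
            if winner is not None:
                signatures[chrom] = _signature(
                    genomes[winner], chrom, origin, winner_markers
                )
                resolved.add(chrom)
                chrom_markers[chrom] = set(winner_markers)
                reps[chrom] = winner
            else:
                reps[chrom] = None
        out[node] = AncestralArrangement(
            node, signatures, resolved, common, chrom_markers, daughter_reps
        )
        rep_tip[node] = reps
        node_markers[node] = common
    return out


# ---------------------------------------------------------------------------
# Whole-pipeline driver
# ---------------------------------------------------------------------------


def run_comparative_analysis(
    maps: dict[str, GeneticMap],
    orthology: OrthologyTable,
    tree: Phylogeny,
    reference: str,
    min_run: int = 2,
    min_block: int = 2,
) -> AnalysisResult:
    ref_map = maps[reference]
    detections = {
        sp: detect_species(maps[sp], ref_map, orthology, min_run, min_block)
        for sp in tree.tips
        if sp != reference
    }
    observations, cluster_members = build_observations(detections, tree, reference)
    assignments = []
    for obs in observations:
        assignments.extend(assign_lineage(obs, tree, reference))
    return AnalysisResult(
        reference=reference,
        detections=detections,
        observations=observations,
        assignments=assignments,
        ancestors={},
        cluster_members=cluster_members,
    )


# ---------------------------------------------------------------------------
# Evaluation against a simulated truth
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    n_true_observable: int = 0
    n_recovered: int = 0
    n_bp_checked: int = 0
    n_bp_contained: int = 0
    n_assignable: int = 0
    n_assigned_correct: int = 0
    n_resolved_chromosomes: int = 0
    n_resolved_correct: int = 0
    n_resolved_unscoreable: int = 0

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_true_observable if self.n_true_observable else 1.0

    @property
    def assignment_accuracy(self) -> float:
        return self.n_assigned_correct / self.n_assignable if self.n_assignable else 1.0

    @property
    def ancestor_accuracy(self) -> float:
        return (
            self.n_resolved_correct / self.n_resolved_chromosomes
            if self.n_resolved_chromosomes
            else 1.0
        )

    def merge(self, other: "EvaluationReport") -> None:
        for name in vars(other):
            setattr(self, name, getattr(self, name) + getattr(other, name))


def _shared_markers(truth: TrueHistory, species: str, reference: str) -> set[str]:
    return truth.retained[species] & truth.retained[reference]


def _observable_block(block: list[str], shared: set[str]) -> list[str]:
    return [m for m in block if m in shared]


def evaluate_against_truth(
    result: AnalysisResult,
    truth: TrueHistory,
    tree: Phylogeny,
    reference: str,
    min_observable: int = 2,
) -> EvaluationReport:
    """Score detection, timing and reconstruction against the history.

    A true event is *observable* when at least one species-vs-reference
    comparison crossing its branch retains >= ``min_observable`` of its
    block markers on both maps.  It is *recovered* when a detected event
    in such a comparison matches it: an exact detection whose block equals
    the observable block, or a lower-bound ("k+") detection overlapping it
    (each k+ event accounts for at most ``min_count`` true events).
    Breakpoint containment is checked for exact matches whose true flanks
    survived dropout.
    """
    report = EvaluationReport()
    det_by_species = result.detections

    # --- recall + breakpoint containment -----------------------------------
    # Each detected event may account for at most max(1, min_count) true
    # events: exact block matches are claimed first, then overlap-based
    # recovery absorbs stacked/overlapping inversions whose individual
    # scenario is not identifiable from sparse markers (they are noticed
    # and counted, which is what the per-branch tallies use).
    budget: dict[tuple[str, int], int] = {}
    for species, det in det_by_species.items():
        for d in det.inversions:
            budget[(species, id(d))] = max(1, d.min_count)

    true_inversions = [
        (branch, ev)
        for branch, events in truth.events.items()
        for ev in events
        if ev.kind == INVERSION
    ]
    observable_of: dict[int, list[tuple[str, list[str]]]] = {}
    recovered: dict[int, bool] = {}
    for branch, true_ev in true_inversions:
        views = []
        for species in tree.tips:
            if species == reference or branch not in tree.path_branches(
                species, reference
            ):
                continue
            shared = _shared_markers(truth, species, reference)
            obs_block = _observable_block(true_ev.block, shared)
            if len(obs_block) >= min_observable:
                views.append((species, obs_block))
        observable_of[id(true_ev)] = views
        recovered[id(true_ev)] = False

    # phase 1: exact block matches
    for branch, true_ev in true_inversions:
        for species, obs_block in observable_of[id(true_ev)]:
            if recovered[id(true_ev)]:
                break
            obs_set = set(obs_block)
            for det in det_by_species[species].inversions:
                key = (species, id(det))
                if (
                    budget[key] > 0
                    and det.exact
                    and set(det.block_markers) == obs_set
                ):
                    budget[key] -= 1
                    recovered[id(true_ev)] = True
                    shared = _shared_markers(truth, species, reference)
                    report.n_bp_checked += 1
                    if _breakpoints_contain(det, true_ev, shared, truth):
                        report.n_bp_contained += 1
                    break

    # phase 2: overlap-based recovery within remaining budgets
    for branch, true_ev in true_inversions:
        if recovered[id(true_ev)]:
            continue
        for species, obs_block in observable_of[id(true_ev)]:
            if recovered[id(true_ev)]:
                break
            obs_set = set(obs_block)
            for det in det_by_species[species].inversions:
                key = (species, id(det))
                if budget[key] > 0 and set(det.block_markers) & obs_set:
                    budget[key] -= 1
                    recovered[id(true_ev)] = True
                    break

    for branch, true_ev in true_inversions:
        if observable_of[id(true_ev)]:
            report.n_true_observable += 1
            if recovered[id(true_ev)]:
                report.n_recovered += 1

    report_tr = _evaluate_translocations(result, truth, tree, reference, min_observable)
    report.n_true_observable += report_tr[0]
    report.n_recovered += report_tr[1]

    _evaluate_assignments(result, truth, tree, reference, report)
    return report


def _breakpoints_contain(
    det: InversionEvent,
    true_ev: TrueEvent,
    shared: set[str],
    truth: TrueHistory,
) -> bool:
    """Detected flanking intervals must bracket the true block: no shared
    marker of the true block may fall outside the detected intervals, and
    surviving true flank markers must sit outside the detected block."""
    lo, hi = det.rank_span
    bp_lo = det.breakpoint_low.left_rank
    bp_hi = det.breakpoint_high.right_rank
    block = set(det.block_markers)
    for flank in (true_ev.left_flank, true_ev.right_flank):
        if flank is not None and flank in shared and flank in block:
            return False
    return bp_lo <= lo and hi <= bp_hi


def _evaluate_translocations(
    result: AnalysisResult,
    truth: TrueHistory,
    tree: Phylogeny,
    reference: str,
    min_observable: int,
) -> tuple[int, int]:
    n_observable = 0
    n_recovered = 0
    for branch, events in truth.events.items():
        for true_ev in events:
            if true_ev.kind != INVERSION:
                observable = False
                recovered = False
                for species in tree.tips:
                    if species == reference or branch not in tree.path_branches(
                        species, reference
                    ):
                        continue
                    shared = _shared_markers(truth, species, reference)
                    blocks = [
                        _observable_block(b, shared) for b in true_ev.blocks
                    ]
                    if not any(len(b) >= min_observable for b in blocks):
                        continue
                    observable = True
                    moved = {m for b in blocks for m in b}
                    det = result.detections[species]
                    for part in det.partitions.values():
                        for seg_ev in part.translocations:
                            boundary = {
                                seg_ev.query_left_marker,
                                seg_ev.query_right_marker,
                            }
                            if boundary & moved:
                                recovered = True
                    if recovered:
                        break
                if observable:
                    n_observable += 1
                    if recovered:
                        n_recovered += 1
    return n_observable, n_recovered


def _evaluate_assignments(
    result: AnalysisResult,
    truth: TrueHistory,
    tree: Phylogeny,
    reference: str,
    report: EvaluationReport,
) -> None:
    """Event-centric branch-assignment accuracy.

    For every true inversion whose carriers (all species whose comparison
    path crosses its branch) each produced an exact detection of its
    block, locate the observation cluster holding those detections.  When
    that cluster's assignment is determined -- i.e. the pattern had an
    informative outgroup -- the assigned branch is scored against the
    true branch.  Events some carrier failed to detect exactly are the
    recall metric's business, not this one's; events whose pattern stayed
    undetermined have no informative outgroup and are out of scope here.
    """
    assignments_of: dict[str, list[LineageAssignment]] = {}
    for a in result.assignments:
        if a.kind == INVERSION:
            assignments_of.setdefault(a.event_id, []).append(a)
    member_cluster: dict[int, str] = {}
    for event_id, members in result.cluster_members.items():
        for m in members:
            member_cluster[id(m)] = event_id

    # per species, the true events visible in its comparison (for the
    # informative-outgroup check below)
    comparison_events: dict[str, list[TrueEvent]] = {}
    for sp in tree.tips:
        if sp == reference:
            continue
        comparison_events[sp] = [
            ev
            for b in tree.path_branches(sp, reference)
            for ev in truth.events.get(b, [])
        ]

    for branch, events in truth.events.items():
        for true_ev in events:
            if true_ev.kind != INVERSION:
                continue
            carriers = [
                sp
                for sp in tree.tips
                if sp != reference and branch in tree.path_branches(sp, reference)
            ]
            # the data must offer an informative outgroup: a non-carrier
            # whose comparison leaves the event's region untouched and
            # which retains enough of the block to vouch for its order
            block = set(true_ev.block)
            has_outgroup = False
            for sp in tree.tips:
                if sp == reference or sp in carriers:
                    continue
                shared = _shared_markers(truth, sp, reference)
                if len(block & shared) < 2:
                    continue
                touched = any(
                    set(b) & block
                    for other in comparison_events[sp]
                    for b in other.blocks
                )
                if not touched:
                    has_outgroup = True
                    break
            if not has_outgroup:
                continue
            cluster_ids = set()
            detected_all = bool(carriers)
            for sp in carriers:
                shared = _shared_markers(truth, sp, reference)
                want = {x for x in true_ev.block if x in shared}
                if len(want) < 2:
                    detected_all = False
                    break
                match = next(
                    (
                        d
                        for d in result.detections[sp].inversions
                        if d.exact and set(d.block_markers) == want
                    ),
                    None,
                )
                if match is None:
                    detected_all = False
                    break
                cluster_ids.add(member_cluster.get(id(match)))
            if not detected_all or len(cluster_ids) != 1:
                continue
            candidates = assignments_of.get(next(iter(cluster_ids)), [])
            assignment = next(
                (a for a in candidates if set(carriers) <= a.carriers),
                None,
            )
            if assignment is None or not assignment.determined:
                continue
            report.n_assignable += 1
            if assignment.branch == branch:
                report.n_assigned_correct += 1


def evaluate_ancestors(
    ancestors: dict[str, AncestralArrangement],
    truth: TrueHistory,
    tree: Phylogeny,
    origin: dict[str, str],
    ref_chromosomes: list[str],
    report: EvaluationReport,
) -> None:
    """Score resolved ancestral chromosomes against the true node genomes.

    The guarantee of correctness holds when every event separating the
    node from its daughter representatives had an *informative outgroup*:
    a species outside the node's clade that (a) carries no event of its
    own touching the chromosome between itself and the node, and (b)
    retains enough of the event's block markers to see it.  Homoplasy and
    outgroup blindness violate that precondition, so chromosomes whose
    daughter-path events lack an informative outgroup are tallied as
    ``n_resolved_unscoreable`` instead of scored -- the data themselves
    cannot warn any method in those cases.
    """

    def touches(ev: TrueEvent, chrom: str) -> bool:
        return any(origin[m] == chrom for b in ev.blocks for m in b)

    for node, anc in ancestors.items():
        true_genome = truth.node_genomes[node]
        outgroups = [t for t in tree.tips if t not in tree.tipset(node)]
        for chrom in anc.resolved:
            markers = anc.chrom_markers.get(chrom, anc.marker_set)
            rep1, rep2 = anc.daughter_reps[chrom]

            scoreable = True
            for rep in (rep1, rep2):
                # branches strictly between rep tip and node
                daughter_path = {
                    b
                    for b in tree.path_branches(rep, outgroups[0])
                    if tree.tipset(b) < tree.tipset(node)
                }
                path_events = [
                    ev
                    for b in daughter_path
                    for ev in truth.events.get(b, [])
                    if touches(ev, chrom)
                ]
                for ev in path_events:
                    witnessed = False
                    for og in outgroups:
                        # outgroup's own path to the comparison must not
                        # touch this chromosome's material
                        og_stem = set(tree.path_branches(og, rep)) - daughter_path
                        if any(
                            touches(e, chrom)
                            for b in og_stem
                            for e in truth.events.get(b, [])
                        ):
                            continue
                        m = anc.marker_set & truth.retained[og]
                        visible = sum(
                            1 for blk in ev.blocks for x in blk if x in m
                        )
                        if visible >= 2:
                            witnessed = True
                            break
                    if not witnessed:
                        scoreable = False
                        break
                if not scoreable:
                    break
            if not scoreable:
                report.n_resolved_unscoreable += 1
                continue
            true_sig = _signature(true_genome, chrom, origin, markers)
            report.n_resolved_chromosomes += 1
            if true_sig == anc.signatures[chrom]:
                report.n_resolved_correct += 1
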