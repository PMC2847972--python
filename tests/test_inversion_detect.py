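from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synkaryo.inversion_detect import (
    CONFIDENT,
    PARACENTRIC,
    PERICENTRIC,
    UNCERTAIN,
    UNCLASSIFIED,
    classify_pericentric,
    detect_inversions,
    replay_events,
)
from synkaryo.map_model_io import ProjectedMarker
from synkaryo.segmentation import ChromosomeSegment

from .conftest import make_tree, identity_orthology


def make_segment(ranks, ref_chrom="R1", species="q", ref_size=None):
    markers = [
        ProjectedMarker(f"q{r}", f"m{r}", ref_chrom, r, 10.0 * i)
        for i, r in enumerate(ranks)
    ]
    return ChromosomeSegment("Q1", "Q1", ref_chrom, markers, species, ref_size)


# --- independent oracles ----------------------------------------------------


def reverse(seq, i, j):
    return seq[:i] + seq[i : j + 1][::-1] + seq[j + 1 :]


def single_reversals_reaching(observed):
    """All single reversals of the sorted order that yield ``observed``."""
    base = sorted(observed)
    n = len(base)
    return [
        (i, j)
        for i, j in combinations(range(n), 2)
        if reverse(base, i, j) == list(observed)
    ]


def two_reversal_scenarios(observed):
    base = sorted(observed)
    n = len(base)
    out = []
    for i1, j1 in combinations(range(n), 2):
        mid = reverse(base, i1, j1)
        for i2, j2 in combinations(range(n), 2):
            if reverse(mid, i2, j2) == list(observed):
                out.append(((i1, j1), (i2, j2)))
    return out


class TestDetect:
    def test_identity_order_no_events(self):
        assert detect_inversions(make_segment([1, 2, 3, 4, 5, 6])) == []

    def test_single_inversion_oracle_confirms_uniqueness(self):
        observed = [1, 2, 5, 4, 3, 6]
        # oracle: exactly one single reversal of the identity produces this
        assert single_reversals_reaching(observed) == [(2, 4)]
        events = detect_inversions(make_segment(observed))
        assert len(events) == 1
        (ev,) = events
        assert ev.rank_span == (3, 5)
        assert ev.block_markers == ["m5", "m4", "m3"]
        assert (ev.breakpoint_low.left_rank, ev.breakpoint_low.right_rank) == (2, 3)
        assert (ev.breakpoint_high.left_rank, ev.breakpoint_high.right_rank) == (5, 6)
        assert ev.confidence == CONFIDENT
        assert ev.exact

    def test_two_disjoint_flips_two_events(self):
        observed = [3, 2, 1, 6, 5, 4]
        # oracle: a two-reversal scenario with the two disjoint blocks exists
        scenarios = two_reversal_scenarios(observed)
        assert (((0, 2), (3, 5))) in scenarios
        events = detect_inversions(make_segment(observed))
        assert len(events) == 2
        assert sorted(ev.rank_span for ev in events) == [(1, 3), (4, 6)]
        assert all(ev.exact for ev in events)

    def test_nested_pair_reported_as_lower_bound(self):
        # invert ranks 3..5 then 2..6 of 1..7: a nested pair whose exact
        # structure is not claimed -- the region gets a "2+" lower bound
        seq = reverse(reverse(list(range(1, 8)), 2, 4), 1, 5)
        # oracle: at least one two-reversal scenario reaches this order,
        # no single reversal does
        assert single_reversals_reaching(seq) == []
        assert two_reversal_scenarios(seq)
        events = detect_inversions(make_segment(seq))
        assert len(events) == 1
        (ev,) = events
        assert not ev.exact
        assert ev.min_count == 2
        assert ev.annotation == "2+"
        assert ev.rank_span == (2, 6)

    def test_under_three_markers_uninformative(self):
        assert detect_inversions(make_segment([2, 1])) == []

    def test_two_marker_flip_uncertain(self):
        events = detect_inversions(make_segment([1, 3, 2, 4]))
        assert len(events) == 1
        assert events[0].confidence == UNCERTAIN
        assert events[0].rank_span == (2, 3)

    def test_wholly_reversed_segment_single_confident_event(self):
        events = detect_inversions(make_segment([5, 4, 3, 2, 1]))
        assert len(events) == 1
        assert events[0].confidence == CONFIDENT
        assert events[0].rank_span == (1, 5)

    def test_irreducible_order_gets_lower_bound(self):
        observed = [2, 4, 1, 3]
        # oracle: neither one nor two reversals of the identity reach this
        # order, so any faithful account needs at least three inversions
        assert single_reversals_reaching(observed) == []
        assert two_reversal_scenarios(observed) == []
        events = detect_inversions(make_segment(observed))
        assert len(events) == 1
        (ev,) = events
        assert not ev.exact
        assert ev.min_count == 3
        assert ev.annotation == "3+"

    def test_ranks_need_not_be_contiguous(self):
        # shared ranks with gaps (markers absent from the query)
        events = detect_inversions(make_segment([2, 9, 7, 4, 12]))
        assert len(events) == 1
        assert events[0].rank_span == (4, 9)
        assert events[0].breakpoint_low.left_rank == 2
        assert events[0].breakpoint_high.right_rank == 12


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(
            lambda t: t[1] - t[0] >= 1
        ),
        min_size=1,
        max_size=2,
    )
)
def test_replay_reproduces_observed_when_all_events_exact(reversals):
    seq = list(range(1, 11))
    for i, j in reversals:
        seq = reverse(seq, i, j)
    segment = make_segment(seq)
    events = detect_inversions(segment)
    if events and all(ev.exact for ev in events):
        assert replay_events(segment, events) == seq


class TestSimulatedSingleInversion:
    def test_recall_and_breakpoint_containment(self):
        import numpy as np

        rng = np.random.default_rng(42)
        n, hits = 0, 0
        for _ in range(120):
            n_markers = 20
            lo = int(rng.integers(0, n_markers - 3))
            hi = int(rng.integers(lo + 3, min(lo + 12, n_markers) + 1))
            base = list(range(1, n_markers + 1))
            observed = reverse(base, lo, hi - 1)
            # dropout <= 20%
            keep = sorted(
                rng.choice(n_markers, size=int(n_markers * 0.8), replace=False)
            )
            seq = [observed[i] for i in keep]
            block = set(base[lo:hi])
            if len(block & set(seq)) < 2:
                continue
            n += 1
            events = detect_inversions(make_segment(seq, ref_size=n_markers))
            match = [
                ev for ev in events
                if ev.exact and set(
                    int(m[1:]) for m in ev.block_markers
                ) == block & set(seq)
            ]
            if match:
                hits += 1
                (ev,) = match
                # detected flanking intervals must contain the true breakpoints
                assert ev.breakpoint_low.left_rank <= lo  # true gap at (lo, lo+1)
                assert ev.breakpoint_low.right_rank >= lo + 1
                assert ev.breakpoint_high.left_rank <= hi
                assert ev.breakpoint_high.right_rank >= hi + 1
        assert n > 60
        assert hits / n >= 0.95


class TestPericentric:
    def test_block_spanning_centromere_is_pericentric(self):
        ev = detect_inversions(make_segment([1, 5, 4, 3, 2, 6]))[0]
        assert classify_pericentric(ev, None, flank_ranks=(3, 4)) == PERICENTRIC

    def test_block_on_one_arm_is_paracentric(self):
        ev = detect_inversions(make_segment([1, 4, 3, 2, 5, 6]))[0]
        assert classify_pericentric(ev, None, flank_ranks=(5, 6)) == PARACENTRIC

    def test_unknown_centromere_unclassified(self, solanaceae_centromeres):
        ev = detect_inversions(make_segment([1, 4, 3, 2, 5], ref_chrom="T99"))[0]
        assert classify_pericentric(ev, solanaceae_centromeres) == UNCLASSIFIED

    def test_fixture_chromosome1_two_pericentric_two_paracentric(
        self, solanaceae_observations, solanaceae_centromeres, solanaceae_reference
    ):
        """The four timing-undetermined chromosome-1 inversions split into
        two pericentric and two paracentric under the fixture centromeres."""
        t1_unknown = [
            o for o in solanaceae_observations
            if o.ref_chromosome == "T1" and o.kind == "inversion"
            and o.states["pepper"] == "E" and o.states["eggplant"] == "R"
        ]
        assert len(t1_unknown) == 4
        flanks = solanaceae_centromeres.flank_ranks("T1", solanaceae_reference)
        peri = sum(
            1 for o in t1_unknown
            if o.span[0] <= flanks[0] and o.span[1] >= flanks[1]
        )
        assert peri == 2


def test_detection_invariant_to_cm_rescaling():
    from synkaryo.map_model_io import GeneticMap, MarkerLocus, project_onto_reference
    from synkaryo.segmentation import partition_segments

    ref = GeneticMap(
        "ref", [MarkerLocus(f"m{i}", "R1", 7.0 * i) for i in range(6)]
    )
    order = ["m0", "m1", "m4", "m3", "m2", "m5"]

    def detect_with_scale(scale):
        q = GeneticMap(
            "q",
            [MarkerLocus(m, "Q1", scale * i) for i, m in enumerate(order)],
        )
        orth = identity_orthology(ref, q)
        proj = project_onto_reference(q, ref, orth)["Q1"]
        (seg,) = partition_segments(proj).segments
        return [
            (ev.rank_span, ev.breakpoint_low.left_rank, ev.breakpoint_high.right_rank)
            for ev in detect_inversions(seg)
        ]

    assert detect_with_scale(1.0) == detect_with_scale(63.5)
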