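from itertools import product

import pytest

from synkaryo.segmentation import BreakpointRegion
from synkaryo.timing_parsimony import (
    HAS_EVENT,
    INDEPENDENT,
    INDEPENDENT_EVENTS,
    INVERSION,
    OUTGROUP_UNINFORMATIVE,
    POSSIBLY_SHARED,
    REF_ORDER,
    REFERENCE_DERIVED,
    SHARED_DERIVED,
    SHARED_EVENT,
    TRANSLOCATION,
    UNINFORMATIVE,
    EventObservation,
    NotComparableError,
    assign_lineage,
    compare_inversions,
    compare_translocations,
    compare_via_reference,
    count_events_by_branch,
    load_observations,
    write_assignments,
)

from .conftest import make_tree

SPECIES = ["tomato", "potato", "eggplant", "pepper", "nicotiana"]


def obs(states, kind=INVERSION, ref_chromosome="T1", span=(3, 6), event_id="ev",
        min_count=1):
    return EventObservation(
        event_id=event_id, kind=kind, ref_chromosome=ref_chromosome,
        span=span, states=dict(states), min_count=min_count,
    )


def pattern(**kw):
    states = {sp: kw.get(sp, REF_ORDER) for sp in SPECIES if sp != "tomato"}
    states.update({k: v for k, v in kw.items() if k in states})
    return states


class TestCompare:
    def test_identical_breakpoint_pairs_shared(self):
        cmp = compare_inversions((3, 6), ((2, 3), (6, 7)), (3, 6), ((2, 3), (6, 7)))
        assert cmp.verdict == SHARED_EVENT

    def test_different_lower_breakpoints_independent(self):
        # one lower breakpoint between g..h, the other between e..g:
        # the open intervals share no gap -> two independent events
        g, h, e = 7, 8, 5
        cmp = compare_inversions((3, g), ((2, 3), (g, h)), (3, e), ((2, 3), (e, g)))
        assert cmp.verdict == INDEPENDENT_EVENTS

    def test_translocation_intervals_narrow_to_overlap(self):
        g, h, i = 7, 8, 9
        cmp = compare_translocations((g, i), (h, i))
        assert cmp.verdict == POSSIBLY_SHARED
        assert cmp.narrowed == (h, i)

    def test_disjoint_translocation_intervals_independent(self):
        assert compare_translocations((2, 3), (7, 9)).verdict == INDEPENDENT_EVENTS

    def test_different_chromosomes_not_comparable(self):
        a = obs(pattern(potato=HAS_EVENT), ref_chromosome="T1")
        b = obs(pattern(potato=HAS_EVENT), ref_chromosome="T2")
        with pytest.raises(NotComparableError):
            compare_via_reference(a, b)

    def test_mixed_kinds_not_comparable(self):
        a = obs(pattern(potato=HAS_EVENT), kind=INVERSION)
        b = obs(pattern(potato=HAS_EVENT), kind=TRANSLOCATION)
        with pytest.raises(NotComparableError):
            compare_via_reference(a, b)

    def test_breakpoint_region_comparison(self):
        a = BreakpointRegion("T3", "m6", "m7", 6, 7)
        b = BreakpointRegion("T3", "m5", "m7", 5, 7)
        assert compare_via_reference(a, b).verdict == POSSIBLY_SHARED


class TestAssignLineage:
    def test_shared_by_potato_and_eggplant_lands_on_tomato_branch(self):
        # pattern of an inversion relative to the reference carried by all
        # informative non-reference species: the reference itself is derived
        tree = make_tree()
        o = obs(pattern(potato=HAS_EVENT, eggplant=HAS_EVENT, pepper=HAS_EVENT,
                        nicotiana=UNINFORMATIVE))
        (a,) = assign_lineage(o, tree, "tomato")
        assert a.branch == "tomato"
        assert a.rationale == REFERENCE_DERIVED

    def test_eggplant_pepper_shared_inversion_lands_on_internal_branch(self):
        tree = make_tree()
        o = obs(pattern(eggplant=HAS_EVENT, pepper=HAS_EVENT,
                        nicotiana=UNINFORMATIVE))
        (a,) = assign_lineage(o, tree, "tomato")
        assert a.branch == "ATPt"
        assert a.rationale == SHARED_DERIVED

    def test_pepper_only_with_blind_distant_outgroup_is_undetermined(self):
        tree = make_tree()
        o = obs(pattern(pepper=HAS_EVENT, nicotiana=UNINFORMATIVE))
        (a,) = assign_lineage(o, tree, "tomato")
        assert a.branch is None
        assert a.candidate_set == frozenset({"ATE", "pepper"})
        assert a.rationale == OUTGROUP_UNINFORMATIVE

    def test_single_carrier_with_informative_outgroups_determined(self):
        tree = make_tree()
        o = obs(pattern(eggplant=HAS_EVENT))
        (a,) = assign_lineage(o, tree, "tomato")
        assert a.branch == "eggplant"

    def test_disconnected_carriers_become_independent_events(self):
        tree = make_tree()
        o = obs(pattern(potato=HAS_EVENT, pepper=HAS_EVENT))
        assignments = assign_lineage(o, tree, "tomato")
        assert len(assignments) == 2
        assert all(a.rationale == INDEPENDENT for a in assignments)
        carried = {frozenset(a.carriers) for a in assignments}
        assert carried == {frozenset({"potato"}), frozenset({"pepper"})}

    def test_nicotiana_only_pattern_splits_root_ambiguity(self):
        tree = make_tree()
        o = obs(pattern(nicotiana=HAS_EVENT))
        (a,) = assign_lineage(o, tree, "tomato")
        assert a.branch is None
        assert a.candidate_set == frozenset({"nicotiana", "ATP"})

    def test_missing_species_state_rejected(self):
        tree = make_tree()
        o = obs({"potato": HAS_EVENT})
        with pytest.raises(ValueError, match="no state"):
            assign_lineage(o, tree, "tomato")

    def test_marking_a_sharer_uninformative_keeps_branch_in_candidates(self):
        tree = make_tree()
        base = pattern(eggplant=HAS_EVENT)
        (a0,) = assign_lineage(obs(base), tree, "tomato")
        assert a0.determined
        for sp in ("potato", "pepper", "nicotiana"):
            weakened = dict(base)
            weakened[sp] = UNINFORMATIVE
            assignments = assign_lineage(obs(weakened), tree, "tomato")
            (a,) = assignments
            assert a0.branch in a.candidate_set


def exhaustive_minimal_placements(tree, states):
    """Brute-force two-state parsimony over all internal labelings and all
    completions of uninformative tips; returns (min changes, branch sets of
    minimal single-change labelings)."""
    internals = [n for n in tree.branches + [tree.root] if not tree.is_tip(n)]
    u_tips = [t for t in tree.tips if states.get(t, REF_ORDER) == UNINFORMATIVE]
    best = None
    single_change_branches = set()
    for internal_states in product("RE", repeat=len(internals)):
        for u_states in product("RE", repeat=len(u_tips)):
            label = dict(zip(internals, internal_states))
            label.update(dict(zip(u_tips, u_states)))
            for t in tree.tips:
                if t not in label:
                    label[t] = states[t]
            changed = [
                b for b in tree.branches if label[b] != label[tree.parent(b)]
            ]
            n = len(changed)
            if best is None or n < best:
                best = n
                single_change_branches = set()
            if n == best == 1:
                single_change_branches.add(changed[0])
    return best, single_change_branches


class TestOracleEquivalence:
    def test_all_two_state_patterns_match_exhaustive_parsimony(self):
        tree = make_tree()
        non_ref = [sp for sp in SPECIES if sp != "tomato"]
        for bits in product([REF_ORDER, HAS_EVENT], repeat=4):
            states = dict(zip(non_ref, bits))
            if HAS_EVENT not in bits:
                continue
            full = dict(states)
            full["tomato"] = REF_ORDER
            best, branches = exhaustive_minimal_placements(tree, full)
            assignments = assign_lineage(obs(states), tree, "tomato")
            if best == 1:
                (a,) = assignments
                assert a.candidate_set == frozenset(branches), states
                assert a.determined == (len(branches) == 1)
            else:
                assert len(assignments) == best, states

    def test_patterns_with_uninformative_tips_match_oracle(self):
        tree = make_tree()
        non_ref = [sp for sp in SPECIES if sp != "tomato"]
        for bits in product([REF_ORDER, HAS_EVENT, UNINFORMATIVE], repeat=4):
            states = dict(zip(non_ref, bits))
            if HAS_EVENT not in bits:
                continue
            full = dict(states)
            full["tomato"] = REF_ORDER
            best, branches = exhaustive_minimal_placements(tree, full)
            assignments = assign_lineage(obs(states), tree, "tomato")
            if best == 1:
                (a,) = assignments
                assert a.candidate_set == frozenset(branches), states
            else:
                assert len(assignments) == best, states


class TestCounting:
    def test_fixture_counts_match_published_totals(
        self, solanaceae_assignments, solanaceae_tree
    ):
        table = count_events_by_branch(solanaceae_assignments, solanaceae_tree)
        assert table.get("tomato", INVERSION).determined == 4
        assert table.get("potato", INVERSION).determined == 2
        assert table.get("ATPt", INVERSION).determined == 4
        assert table.get("eggplant", INVERSION).determined == 16
        assert table.n_undetermined(INVERSION, {"ATE", "pepper"}) == 11

    def test_empty_assignment_list_all_zero(self, solanaceae_tree):
        table = count_events_by_branch([], solanaceae_tree)
        assert all(
            bc.count_min == 0 and bc.count_max == 0
            for bc in table.counts.values()
        )

    def test_sum_invariant(self, solanaceae_assignments, solanaceae_tree):
        table = count_events_by_branch(solanaceae_assignments, solanaceae_tree)
        for kind in (INVERSION, TRANSLOCATION):
            determined = sum(
                bc.determined
                for (b, k), bc in table.counts.items()
                if k == kind
            )
            undetermined = table.n_undetermined(kind)
            total = sum(
                a.min_count for a in solanaceae_assignments if a.kind == kind
            )
            assert determined + undetermined == total

    def test_undetermined_contribute_to_max_of_each_candidate(self, solanaceae_tree):
        o = obs(pattern(pepper=HAS_EVENT, nicotiana=UNINFORMATIVE))
        (a,) = assign_lineage(o, solanaceae_tree, "tomato")
        table = count_events_by_branch([a], solanaceae_tree)
        assert table.get("pepper", INVERSION).count_max == 1
        assert table.get("ATE", INVERSION).count_max == 1
        assert table.get("pepper", INVERSION).count_min == 0


class TestObservationIO:
    def test_load_observations_fixture(self, solanaceae_observations):
        assert len(solanaceae_observations) == 62
        inv = [o for o in solanaceae_observations if o.kind == INVERSION]
        tr = [o for o in solanaceae_observations if o.kind == TRANSLOCATION]
        assert len(inv) == 39
        assert len(tr) == 23

    def test_observation_requires_a_carrier(self):
        with pytest.raises(ValueError, match="no species carries"):
            obs(pattern())

    def test_write_assignments(self, tmp_path, solanaceae_assignments):
        out = tmp_path / "a.tsv"
        write_assignments(solanaceae_assignments, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("event_id\t")
        assert len(lines) == len(solanaceae_assignments) + 1
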