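import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synkaryo.map_model_io import (
    GeneticMap,
    MapFormatError,
    MarkerLocus,
    OrthologyTable,
    load_map,
    load_orthology,
    project_onto_reference,
    write_map,
)

from .conftest import make_map, make_tree, identity_orthology


def write_tsv(tmp_path, name, body):
    path = tmp_path / name
    path.write_text(textwrap.dedent(body))
    return path


MAP_HEADER = "species\tchromosome\tmarker\tposition_cM\tconfidence\n"


class TestLoadMap:
    def test_basic_three_markers(self, tmp_path):
        path = write_tsv(
            tmp_path, "m.tsv",
            MAP_HEADER
            + "egg\tE1\ta\t0\thigh\negg\tE1\tb\t5\thigh\negg\tE1\tc\t9\thigh\n",
        )
        m = load_map(path)
        assert m.species_id == "egg"
        assert m.chromosomes == ["E1"]
        assert [l.marker_id for l in m.loci("E1")] == ["a", "b", "c"]

    def test_named_marker_retrievable(self, tmp_path):
        path = write_tsv(
            tmp_path, "m.tsv",
            MAP_HEADER + "eggplant\tE4\tTG386\t42.0\thigh\n"
            "eggplant\tE4\tT677\t44.5\thigh\n",
        )
        m = load_map(path)
        assert "TG386" in m
        assert m["TG386"].chromosome == "E4"
        assert m["TG386"].position == 42.0

    def test_header_only_errors_no_loci(self, tmp_path):
        path = write_tsv(tmp_path, "m.tsv", MAP_HEADER)
        with pytest.raises(MapFormatError, match="no loci"):
            load_map(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = write_tsv(
            tmp_path, "m.tsv", MAP_HEADER + "egg\tE1\ta\t0\thigh\negg\tE1\tb\n"
        )
        with pytest.raises(MapFormatError, match=r":3"):
            load_map(path)

    def test_negative_position_rejected(self, tmp_path):
        path = write_tsv(tmp_path, "m.tsv", MAP_HEADER + "egg\tE1\ta\t-1\thigh\n")
        with pytest.raises(MapFormatError, match="negative"):
            load_map(path)

    def test_duplicate_row_rejected(self, tmp_path):
        path = write_tsv(
            tmp_path, "m.tsv",
            MAP_HEADER + "egg\tE1\ta\t0\thigh\negg\tE1\ta\t3\thigh\n",
        )
        with pytest.raises(MapFormatError, match="duplicate"):
            load_map(path)

    def test_non_numeric_position(self, tmp_path):
        path = write_tsv(tmp_path, "m.tsv", MAP_HEADER + "egg\tE1\ta\tNaNope\thigh\n")
        with pytest.raises(MapFormatError, match="not a number"):
            load_map(path)

    def test_round_trip(self, tmp_path):
        m = make_map("sp", {"c1": ["a", "b", "c"], "c2": ["d", "e"]}, low={"b"})
        out = tmp_path / "rt.tsv"
        write_map(m, out)
        m2 = load_map(out)
        assert m2.species_id == m.species_id
        assert m2.chromosomes == m.chromosomes
        for chrom in m.chromosomes:
            assert [(l.marker_id, l.position, l.confidence) for l in m.loci(chrom)] == [
                (l.marker_id, l.position, l.confidence) for l in m2.loci(chrom)
            ]


class TestGeneticMap:
    def test_cosegregating_tie_broken_lexicographically(self):
        loci = [
            MarkerLocus("zeta", "c1", 5.0),
            MarkerLocus("alpha", "c1", 5.0),
            MarkerLocus("mid", "c1", 1.0),
        ]
        m = GeneticMap("sp", loci)
        assert [l.marker_id for l in m.loci("c1")] == ["mid", "alpha", "zeta"]

    def test_rank_table_excludes_low_confidence(self):
        m = make_map("sp", {"c1": ["a", "b", "c"]}, low={"b"})
        assert m.rank_table("c1") == {"a": 1, "c": 2}
        assert m.rank_table("c1", include_low=True) == {"a": 1, "b": 2, "c": 3}

    def test_empty_map_rejected(self):
        with pytest.raises(MapFormatError, match="no loci"):
            GeneticMap("sp", [])

    def test_bad_confidence_rejected(self):
        with pytest.raises(MapFormatError):
            MarkerLocus("a", "c1", 0.0, confidence="medium")


class TestOrthology:
    def test_singleton_classes_dropped(self):
        table = OrthologyTable(
            {"g1": {"a": "m1", "b": "m2"}, "g2": {"a": "m3"}}
        )
        assert len(table.groups) == 1
        assert table.n_dropped_singletons == 1

    def test_marker_in_two_classes_rejected(self):
        with pytest.raises(MapFormatError, match="two classes"):
            OrthologyTable(
                {"g1": {"a": "m1", "b": "m2"}, "g2": {"a": "m1", "b": "m9"}}
            )

    def test_shared_markers(self):
        table = OrthologyTable(
            {"g1": {"a": "m1", "b": "n1"}, "g2": {"a": "m2", "c": "p2"}}
        )
        assert table.shared_markers("a", "b") == {"m1": "n1"}

    def test_load(self, tmp_path):
        path = write_tsv(
            tmp_path, "o.tsv",
            "group_id\tspecies\tmarker\ng1\ta\tm1\ng1\tb\tn1\n",
        )
        table = load_orthology(path)
        assert table.shared_markers("a", "b") == {"m1": "n1"}


class TestProjection:
    def test_same_order_single_reference_chromosome(self):
        ref = make_map("ref", {"R1": ["m1", "m2", "m3", "m4", "m5", "m6"]})
        query = make_map("q", {"Q1": ["m1", "m2", "m3", "m4", "m5", "m6"]})
        proj = project_onto_reference(query, ref, identity_orthology(ref, query))
        p = proj["Q1"]
        assert p.reference_chromosomes == ["R1"]
        assert [m.ref_rank for m in p.markers] == [1, 2, 3, 4, 5, 6]

    def test_two_reference_chromosomes(self):
        # query chromosome mixing material from two reference chromosomes
        ref = make_map("ref", {"T10": ["x1", "x2", "x3"], "T4": ["y1", "y2", "y3"]})
        query = make_map("q", {"E4": ["x1", "x2", "y1", "y2", "y3"]})
        proj = project_onto_reference(query, ref, identity_orthology(ref, query))
        assert proj["E4"].reference_chromosomes == ["T10", "T4"]

    def test_low_confidence_excluded(self):
        ref = make_map("ref", {"R1": ["a", "b", "c"]})
        query = make_map("q", {"Q1": ["a", "b", "c"]}, low={"b"})
        proj = project_onto_reference(query, ref, identity_orthology(ref, query))
        assert [m.query_marker for m in proj["Q1"].markers] == ["a", "c"]

    def test_no_shared_markers_flagged_uninformative(self):
        ref = make_map("ref", {"R1": ["a", "b"]})
        query = make_map("q", {"Q1": ["x", "y"]})
        proj = project_onto_reference(query, ref, identity_orthology(ref, query))
        assert proj["Q1"].uninformative

    def test_projection_order_follows_query_positions(self):
        ref = make_map("ref", {"R1": ["a", "b", "c", "d"]})
        query = make_map("q", {"Q1": ["d", "b", "a", "c"]})
        proj = project_onto_reference(query, ref, identity_orthology(ref, query))
        assert [m.query_marker for m in proj["Q1"].markers] == ["d", "b", "a", "c"]
        assert [m.ref_rank for m in proj["Q1"].markers] == [4, 2, 1, 3]

    def test_simulated_dropout_projection_contains_exact_survivors(self):
        from synkaryo.synthetic_data import SimulationParams, simulate

        tree = make_tree()
        params = SimulationParams(
            tree=tree, chromosomes=3, markers_per_chromosome=12,
            inversion_rate=0.0, translocation_rate=0.0, dropout=0.3, seed=7,
        )
        maps, truth = simulate(params)
        orth = identity_orthology(*maps.values())
        proj = project_onto_reference(maps["pepper"], maps["tomato"], orth)
        projected = {m.query_marker for p in proj.values() for m in p.markers}
        expected = truth.retained["pepper"] & truth.retained["tomato"]
        assert projected == expected


class TestPhylogeny:
    def test_ages_and_durations(self, solanaceae_tree):
        t = solanaceae_tree
        assert t.root == "ATN"
        assert sorted(t.tips) == [
            "eggplant", "nicotiana", "pepper", "potato", "tomato",
        ]
        assert t.branch_duration("tomato") == pytest.approx(7.3)
        assert t.branch_duration("ATPt") == pytest.approx(8.2)
        assert t.branch_duration("ATE") == pytest.approx(4.1)

    def test_root_to_tip_paths_sum_to_root_age(self, solanaceae_tree):
        t = solanaceae_tree
        for tip in t.tips:
            total, node = 0.0, tip
            while t.parent(node) is not None:
                total += t.branch_duration(node)
                node = t.parent(node)
            assert total == pytest.approx(23.7)

    def test_child_older_than_parent_rejected(self):
        with pytest.raises(MapFormatError, match="younger"):
            make_tree(ages={"ATPt": 30.0, "ATE": 15.5, "ATP": 19.6, "ATN": 23.7})

    def test_missing_internal_age_rejected(self):
        with pytest.raises(MapFormatError, match="no age"):
            make_tree(ages={"ATPt": 7.3})

    def test_tipsets_and_paths(self, solanaceae_tree):
        t = solanaceae_tree
        assert t.tipset("ATPt") == {"tomato", "potato"}
        assert set(t.path_branches("tomato", "eggplant")) == {
            "tomato", "ATPt", "eggplant",
        }
        assert t.mrca(["tomato", "pepper"]) == "ATP"


class TestCentromeres:
    def test_flank_ranks(self, solanaceae_centromeres, solanaceae_reference):
        assert solanaceae_centromeres.flank_ranks("T3", solanaceae_reference) == (10, 11)

    def test_validate_positions_inside_span(
        self, solanaceae_centromeres, solanaceae_reference
    ):
        solanaceae_centromeres.validate(solanaceae_reference)


@settings(max_examples=40, deadline=None)
@given(
    order=st.permutations(list(range(8))),
    scale=st.floats(min_value=0.1, max_value=25.0),
)
def test_projection_rank_sequence_invariant_to_cm_rescaling(order, scale):
    """Ranks depend on order only, never on the cM scale of either map."""
    markers = [f"m{i}" for i in range(8)]
    ref = make_map("ref", {"R1": markers})
    loci_a = [MarkerLocus(markers[j], "Q1", 3.0 * i) for i, j in enumerate(order)]
    loci_b = [
        MarkerLocus(markers[j], "Q1", 3.0 * i * scale) for i, j in enumerate(order)
    ]
    qa, qb = GeneticMap("qa", loci_a), GeneticMap("qb", loci_b)
    orth_a = identity_orthology(ref, qa)
    ranks_a = [m.ref_rank for m in project_onto_reference(qa, ref, orth_a)["Q1"].markers]
    orth_b = identity_orthology(ref, qb)
    ranks_b = [m.ref_rank for m in project_onto_reference(qb, ref, orth_b)["Q1"].markers]
    assert ranks_a == ranks_b
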