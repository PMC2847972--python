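from __future__ import annotations

import dendropy
import pytest

from synkaryo.map_model_io import (
    GeneticMap,
    MarkerLocus,
    OrthologyTable,
    Phylogeny,
    load_centromeres,
    load_map,
    load_tree,
)
from synkaryo.synthetic_data import fixture_path
from synkaryo.timing_parsimony import load_observations

SOLANACEAE_NEWICK = (
    "((((tomato:7.3,potato:7.3)ATPt:8.2,eggplant:15.5)ATE:4.1,"
    "pepper:19.6)ATP:4.1,nicotiana:23.7)ATN;"
)
SOLANACEAE_AGES = {"ATPt": 7.3, "ATE": 15.5, "ATP": 19.6, "ATN": 23.7}


def make_tree(newick: str = SOLANACEAE_NEWICK, ages: dict | None = None) -> Phylogeny:
    return Phylogeny(
        dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        ),
        ages or SOLANACEAE_AGES,
    )


def make_map(species: str, chrom_markers: dict[str, list[str]],
             low: set[str] | None = None) -> GeneticMap:
    """Build a map from ordered marker lists; positions 10 cM apart."""
    low = low or set()
    loci = []
    for chrom, markers in chrom_markers.items():
        for i, marker in enumerate(markers):
            loci.append(
                MarkerLocus(
                    marker, chrom, 10.0 * i,
                    "low" if marker in low else "high",
                )
            )
    return GeneticMap(species, loci)


def identity_orthology(*maps: GeneticMap) -> OrthologyTable:
    return OrthologyTable.identity(maps)


@pytest.fixture(scope="session")
def solanaceae_tree() -> Phylogeny:
    return load_tree(
        fixture_path("solanaceae_tree.nwk"), fixture_path("solanaceae_config.yaml")
    )


@pytest.fixture(scope="session")
def solanaceae_observations():
    return load_observations(fixture_path("solanaceae_observations.tsv"))


@pytest.fixture(scope="session")
def solanaceae_reference():
    return load_map(fixture_path("solanaceae_reference_map.tsv"))


@pytest.fixture(scope="session")
def solanaceae_centromeres():
    return load_centromeres(fixture_path("solanaceae_centromeres.tsv"))


@pytest.fixture(scope="session")
def solanaceae_assignments(solanaceae_observations, solanaceae_tree):
    from synkaryo.timing_parsimony import assign_lineage

    return [
        a
        for obs in solanaceae_observations
        for a in assign_lineage(obs, solanaceae_tree, "tomato")
    ]
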