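"""Domain types and I/O for genetic maps, marker orthology and dated phylogenies.

The raw observable of the whole pipeline is a set of per-species genetic
maps: ordered marker positions (centimorgans) per chromosome.  Because cM
scales are not comparable between species, every downstream computation is
*rank* based: a species map is projected onto a chosen reference map and
each shared marker is annotated with the reference chromosome it belongs to
and its 1-based order index ("rank") on that reference chromosome.

File formats (all plain TSV, header required):

* map file            -- species, chromosome, marker, position_cM, confidence
* orthology file      -- group_id, species, marker
* centromere file     -- chromosome, position_cM, left_marker, right_marker
* tree                -- Newick with labelled internal nodes; node ages (MY)
                         come from a YAML config (``node_ages: {...}``)
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import yaml

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["species", "chromosome", "marker", "position_cM", "confidence"]
ORTHOLOGY_COLUMNS = ["group_id", "species", "marker"]
CENTROMERE_COLUMNS = ["chromosome", "position_cM", "left_marker", "right_marker"]

HIGH = "high"
LOW = "low"


class MapFormatError(ValueError):
    """Raised for malformed input tables; message names the offending line."""


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerLocus:
    """A single mapped marker on one chromosome of one species map."""

    marker_id: str
    chromosome: str
    position: float  # centimorgans
    confidence: str = HIGH

    def __post_init__(self) -> None:
        if self.position < 0:
            raise MapFormatError(
                f"marker {self.marker_id!r}: negative position {self.position}"
            )
        if self.confidence not in (HIGH, LOW):
            raise MapFormatError(
                f"marker {self.marker_id!r}: confidence must be 'high' or 'low', "
                f"got {self.confidence!r}"
            )


class GeneticMap:
    """Ordered marker positions for one species.

    Within a chromosome, loci sort by cM position; co-segregating markers
    (position ties) are broken by marker id, lexicographically.  The true
    order of co-segregating markers is unknowable from a genetic map, so
    the tie-break is a documented convention, not an inference.
    """

    def __init__(self, species_id: str, loci: Iterable[MarkerLocus]):
        self.species_id = species_id
        self._by_id: dict[str, MarkerLocus] = {}
        self._by_chrom: dict[str, list[MarkerLocus]] = {}
        for locus in loci:
            if locus.marker_id in self._by_id:
                raise MapFormatError(
                    f"{species_id}: duplicate marker {locus.marker_id!r}"
                )
            self._by_id[locus.marker_id] = locus
            self._by_chrom.setdefault(locus.chromosome, []).append(locus)
        if not self._by_chrom:
            raise MapFormatError(f"{species_id}: no loci")
        for chrom_loci in self._by_chrom.values():
            chrom_loci.sort(key=lambda l: (l.position, l.marker_id))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def loci(self, chromosome: str) -> list[MarkerLocus]:
        """Loci of one chromosome in map order (position, then marker id)."""
        return list(self._by_chrom[chromosome])

    def all_loci(self) -> Iterator[MarkerLocus]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._by_id

    def __getitem__(self, marker_id: str) -> MarkerLocus:
        return self._by_id[marker_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def rank_table(self, chromosome: str, include_low: bool = False) -> dict[str, int]:
        """1-based order index of every marker on ``chromosome``."""
        loci = self._by_chrom[chromosome]
        if not include_low:
            loci = [l for l in loci if l.confidence == HIGH]
        return {l.marker_id: i + 1 for i, l in enumerate(loci)}


def load_map(path: str | Path) -> GeneticMap:
    """Read a species map from a 5-column TSV file.

    Raises :class:`MapFormatError` for malformed rows (naming the line),
    negative positions, duplicate (chromosome, marker) rows, or a file with
    no data rows.
    """
    path = Path(path)
    loci: list[MarkerLocus] = []
    species: str | None = None
    seen: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = _read_header(reader, path, MAP_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) != len(header):
                raise MapFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            sp, chrom, marker, pos_s, conf = (f.strip() for f in row)
            if species is None:
                species = sp
            elif sp != species:
                raise MapFormatError(
                    f"{path}:{lineno}: mixed species {sp!r} and {species!r} in one map file"
                )
            try:
                pos = float(pos_s)
            except ValueError as exc:
                raise MapFormatError(
                    f"{path}:{lineno}: position_cM {pos_s!r} is not a number"
                ) from exc
            if pos < 0:
                raise MapFormatError(f"{path}:{lineno}: negative position {pos}")
            key = (chrom, marker)
            if key in seen:
                raise MapFormatError(
                    f"{path}:{lineno}: duplicate row for marker {marker!r} on {chrom}"
                )
            seen.add(key)
            loci.append(MarkerLocus(marker, chrom, pos, conf or HIGH))
    if not loci:
        raise MapFormatError(f"{path}: no loci")
    assert species is not None
    return GeneticMap(species, loci)


def write_map(genetic_map: GeneticMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MAP_COLUMNS)
        for locus in genetic_map.all_loci():
            writer.writerow(
                [
                    genetic_map.species_id,
                    locus.chromosome,
                    locus.marker_id,
                    f"{locus.position:g}",
                    locus.confidence,
                ]
            )


def _read_header(reader, path: Path, expected: Sequence[str]) -> list[str]:
    try:
        header = next(reader)
    except StopIteration:
        raise MapFormatError(f"{path}: empty file") from None
    header = [h.strip() for h in header]
    if header != list(expected):
        raise MapFormatError(
            f"{path}:1: bad header {header!r}, expected {list(expected)!r}"
        )
    return header


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------


class OrthologyTable:
    """1:1 single-copy orthology classes linking markers across species.

    Each class maps at most one marker per species.  Classes with fewer
    than two species carry no comparative signal and are dropped (with a
    logged count).  A marker may appear in one class only.
    """

    def __init__(self, groups: Mapping[str, Mapping[str, str]]):
        self.groups: dict[str, dict[str, str]] = {}
        seen: set[tuple[str, str]] = set()
        dropped = 0
        for gid, members in groups.items():
            if len(members) < 2:
                dropped += 1
                continue
            for sp, marker in members.items():
                key = (sp, marker)
                if key in seen:
                    raise MapFormatError(
                        f"orthology: marker {marker!r} ({sp}) appears in two classes"
                    )
                seen.add(key)
            self.groups[gid] = dict(members)
        self.n_dropped_singletons = dropped
        if dropped:
            logger.info("orthology: dropped %d classes with <2 species", dropped)

    def shared_markers(self, species_a: str, species_b: str) -> dict[str, str]:
        """Map of species_a marker id -> species_b marker id."""
        out = {}
        for members in self.groups.values():
            if species_a in members and species_b in members:
                out[members[species_a]] = members[species_b]
        return out

    @classmethod
    def identity(cls, maps: Iterable[GeneticMap]) -> "OrthologyTable":
        """Orthology by shared marker names (used for simulated data)."""
        by_marker: dict[str, dict[str, str]] = {}
        for m in maps:
            for locus in m.all_loci():
                by_marker.setdefault(locus.marker_id, {})[m.species_id] = locus.marker_id
        return cls({f"g_{mid}": members for mid, members in sorted(by_marker.items())})


def load_orthology(path: str | Path) -> OrthologyTable:
    path = Path(path)
    groups: dict[str, dict[str, str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        _read_header(reader, path, ORTHOLOGY_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) != 3:
                raise MapFormatError(
                    f"{path}:{lineno}: expected 3 fields, got {len(row)}"
                )
            gid, sp, marker = (f.strip() for f in row)
            members = groups.setdefault(gid, {})
            if sp in members:
                raise MapFormatError(
                    f"{path}:{lineno}: class {gid!r} already has a marker for {sp!r}"
                )
            members[sp] = marker
    return OrthologyTable(groups)


def write_orthology(table: OrthologyTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ORTHOLOGY_COLUMNS)
        for gid in sorted(table.groups):
            for sp in sorted(table.groups[gid]):
                writer.writerow([gid, sp, table.groups[gid][sp]])


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted, dated tree over species ids.

    Every non-root node (tip or internal) defines a *branch* to its parent,
    named by the node's label.  Node ages are in MY; tips have age 0, a
    child is younger than its parent, so all branch durations are positive.
    """

    def __init__(self, tree: dendropy.Tree, node_ages: Mapping[str, float]):
        self._tree = tree
        self.node_ages: dict[str, float] = {}
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, list[str]] = {}
        self._tipset: dict[str, frozenset[str]] = {}

        for node in tree.preorder_node_iter():
            name = _node_name(node)
            if name is None:
                raise MapFormatError("phylogeny: every internal node must be labelled")
            if node.is_leaf():
                age = float(node_ages.get(name, 0.0))
            else:
                if name not in node_ages:
                    raise MapFormatError(f"phylogeny: no age for internal node {name!r}")
                age = float(node_ages[name])
            self.node_ages[name] = age
            parent = _node_name(node.parent_node) if node.parent_node else None
            self._parent[name] = parent
            self._children.setdefault(name, [])
            if parent is not None:
                self._children[parent].append(name)

        for node in tree.postorder_node_iter():
            name = _node_name(node)
            if node.is_leaf():
                self._tipset[name] = frozenset([name])
            else:
                self._tipset[name] = frozenset().union(
                    *(self._tipset[c] for c in self._children[name])
                )

        self.root = _node_name(tree.seed_node)
        for name, parent in self._parent.items():
            if parent is not None and self.node_ages[name] >= self.node_ages[parent]:
                raise MapFormatError(
                    f"phylogeny: node {name!r} (age {self.node_ages[name]}) is not "
                    f"younger than its parent {parent!r} ({self.node_ages[parent]})"
                )

    @property
    def tips(self) -> list[str]:
        return sorted(t for t, ts in self._tipset.items() if ts == {t})

    @property
    def branches(self) -> list[str]:
        """All non-root node names, each naming the branch to its parent."""
        return [n for n in self._parent if self._parent[n] is not None]

    def parent(self, name: str) -> str | None:
        return self._parent[name]

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def tipset(self, name: str) -> frozenset[str]:
        """Tips descending from (and including) ``name``."""
        return self._tipset[name]

    def branch_duration(self, name: str) -> float:
        parent = self._parent[name]
        if parent is None:
            raise ValueError(f"{name!r} is the root; it has no branch")
        return self.node_ages[parent] - self.node_ages[name]

    def is_tip(self, name: str) -> bool:
        return self._tipset[name] == {name}

    def path_branches(self, tip_a: str, tip_b: str) -> list[str]:
        """Branches on the tree path between two tips."""
        anc_a = self._ancestry(tip_a)
        anc_b = self._ancestry(tip_b)
        common = [n for n in anc_a if n in set(anc_b)]
        mrca = common[0]
        path = []
        for anc in (anc_a, anc_b):
            for n in anc:
                if n == mrca:
                    break
                path.append(n)
        return path

    def mrca(self, tips: Iterable[str]) -> str:
        tips = list(tips)
        sets = [self._ancestry(t) for t in tips]
        first = sets[0]
        rest = [set(s) for s in sets[1:]]
        for n in first:
            if all(n in r for r in rest):
                return n
        raise ValueError("disjoint tips")  # pragma: no cover

    def _ancestry(self, name: str) -> list[str]:
        out = [name]
        while self._parent[out[-1]] is not None:
            out.append(self._parent[out[-1]])
        return out


def _node_name(node: dendropy.Node | None) -> str | None:
    if node is None:
        return None
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def load_tree(newick_path: str | Path, config_path: str | Path) -> Phylogeny:
    """Load a Newick tree plus a YAML config with ``node_ages``."""
    tree = dendropy.Tree.get(
        path=str(newick_path), schema="newick", suppress_internal_node_taxa=True
    )
    with Path(config_path).open() as fh:
        config = yaml.safe_load(fh) or {}
    ages = config.get("node_ages")
    if not isinstance(ages, dict):
        raise MapFormatError(f"{config_path}: missing 'node_ages' mapping")
    return Phylogeny(tree, ages)


# ---------------------------------------------------------------------------
# Centromeres
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CentromerePosition:
    chromosome: str
    position: float
    left_marker: str
    right_marker: str


class CentromereTable:
    """Reference centromere positions with their flanking marker pair."""

    def __init__(self, entries: Iterable[CentromerePosition]):
        self._entries = {e.chromosome: e for e in entries}

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._entries

    def __getitem__(self, chromosome: str) -> CentromerePosition:
        return self._entries[chromosome]

    def flank_ranks(self, chromosome: str, reference: GeneticMap) -> tuple[int, int]:
        """Rank interval (left, right) of the centromere on the reference map."""
        entry = self._entries[chromosome]
        ranks = reference.rank_table(chromosome)
        left, right = ranks[entry.left_marker], ranks[entry.right_marker]
        if left >= right:
            raise MapFormatError(
                f"centromere {chromosome}: flanking markers out of order"
            )
        return left, right

    def validate(self, reference: GeneticMap) -> None:
        for chrom, entry in self._entries.items():
            loci = reference.loci(chrom)
            lo, hi = loci[0].position, loci[-1].position
            if not lo <= entry.position <= hi:
                raise MapFormatError(
                    f"centromere {chrom}: position {entry.position} outside marker "
                    f"span [{lo}, {hi}]"
                )


def load_centromeres(path: str | Path) -> CentromereTable:
    path = Path(path)
    entries = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        _read_header(reader, path, CENTROMERE_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row or row[0].lstrip().startswith("#"):
                continue
            chrom, pos_s, left, right = (f.strip() for f in row)
            try:
                pos = float(pos_s)
            except ValueError as exc:
                raise MapFormatError(
                    f"{path}:{lineno}: position_cM {pos_s!r} is not a number"
                ) from exc
            entries.append(CentromerePosition(chrom, pos, left, right))
    return CentromereTable(entries)


# ---------------------------------------------------------------------------
# Reference projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectedMarker:
    """One shared marker of a query chromosome, in query-map order."""

    query_marker: str
    ref_marker: str
    ref_chromosome: str
    ref_rank: int  # 1-based order index on the reference chromosome
    query_position: float


@dataclass
class ReferenceProjection:
    """Ordered shared markers of one query chromosome, painted by reference.

    Contains only high-confidence markers present on both maps; marker
    order equals position order on the *query* map.  ``uninformative`` is
    set when the chromosome shares no markers with the reference.
    """

    species_id: str
    chromosome: str
    markers: list[ProjectedMarker] = field(default_factory=list)
    ref_sizes: dict[str, int] = field(default_factory=dict)  # ref chrom -> n markers

    @property
    def uninformative(self) -> bool:
        return not self.markers

    @property
    def reference_chromosomes(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.ref_chromosome not in seen:
                seen.append(m.ref_chromosome)
        return seen


def project_onto_reference(
    query: GeneticMap, reference: GeneticMap, orthology: OrthologyTable
) -> dict[str, ReferenceProjection]:
    """Project a species map onto the reference marker order.

    Returns one :class:`ReferenceProjection` per query chromosome.  Ranks
    are order indices over *all* high-confidence markers of the reference
    chromosome, so breakpoint intervals narrow as reference density grows.
    Low-confidence markers (on either map) are excluded and logged.
    """
    marker_map = orthology.shared_markers(query.species_id, reference.species_id)
    ref_ranks = {
        chrom: reference.rank_table(chrom) for chrom in reference.chromosomes
    }
    ref_sizes = {chrom: len(ranks) for chrom, ranks in ref_ranks.items()}
    ref_chrom_of = {
        locus.marker_id: locus.chromosome for locus in reference.all_loci()
    }
    n_low = 0
    projections: dict[str, ReferenceProjection] = {}
    for chrom in query.chromosomes:
        projected: list[ProjectedMarker] = []
        for locus in query.loci(chrom):
            ref_marker = marker_map.get(locus.marker_id)
            if ref_marker is None or ref_marker not in reference:
                continue
            if locus.confidence == LOW or reference[ref_marker].confidence == LOW:
                n_low += 1
                continue
            ref_chrom = ref_chrom_of[ref_marker]
            projected.append(
                ProjectedMarker(
                    query_marker=locus.marker_id,
                    ref_marker=ref_marker,
                    ref_chromosome=ref_chrom,
                    ref_rank=ref_ranks[ref_chrom][ref_marker],
                    query_position=locus.position,
                )
            )
        proj = ReferenceProjection(query.species_id, chrom, projected, dict(ref_sizes))
        if proj.uninformative:
            logger.info(
                "%s %s: no shared markers with %s (uninformative)",
                query.species_id, chrom, reference.species_id,
            )
        projections[chrom] = proj
    if n_low:
        logger.info(
            "%s vs %s: excluded %d low-confidence marker observations",
            query.species_id, reference.species_id, n_low,
        )
    return projections
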