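"""Simulate marker-map evolution along a dated phylogeny.

Markers are atoms with identity; a genome is an ordered arrangement of
markers over a fixed number of chromosomes (chromosome number never
changes -- no fissions/fusions).  Along every branch, inversion and
translocation counts are Poisson(rate x branch duration); breakpoints
fall between marker gaps, drawn uniformly or from a hotspot model.  After
evolution, each species independently loses a random subset of markers
("dropout": different subsets are mapped in different species) and cM
positions are assigned by cumulative uniform gaps.

Everything is driven by one seeded generator: a fixed seed reproduces
the whole dataset bit-exactly.  The emitted :class:`TrueHistory` is the
oracle every detection/timing/reconstruction module is tested against.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .map_model_io import GeneticMap, MarkerLocus, OrthologyTable, Phylogeny

INVERSION = "inversion"
TRANSLOCATION = "translocation"

Genome = list[list[str]]  # chromosomes -> ordered marker ids


@dataclass
class HotspotModel:
    """Breakpoint weights concentrated at fractional positions (0..1)."""

    positions: list[float]
    weight: float = 10.0  # relative weight of each hotspot gap vs background


@dataclass
class SimulationParams:
    tree: Phylogeny
    chromosomes: int = 12
    markers_per_chromosome: int = 40
    inversion_rate: float = 0.5  # events / MY / lineage (whole genome)
    translocation_rate: float = 0.3
    reciprocal_fraction: float = 0.7  # rest are insertional
    dropout: float = 0.2
    reference: str = "tomato"
    reference_full: bool = True  # the reference map keeps all markers
    hotspots: HotspotModel | None = None
    min_inversion_block: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inversion_rate < 0 or self.translocation_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.markers_per_chromosome < 4:
            raise ValueError("need >= 4 markers per chromosome")
        if self.reference not in self.tree.tips:
            raise ValueError(f"reference {self.reference!r} is not a tip")


@dataclass
class TrueEvent:
    kind: str
    branch: str
    chromosome_index: int  # position in the genome at event time
    block: list[str]  # markers moved/reversed, in pre-event order
    left_flank: str | None  # marker just before the block at event time
    right_flank: str | None
    detail: str = ""  # reciprocal | insertional | '' for inversions
    # second junction of a translocation (other chromosome involved)
    block2: list[str] = field(default_factory=list)
    chromosome_index2: int | None = None
    insertion_index: int | None = None  # recipient gap of an insertional event

    @property
    def blocks(self) -> list[list[str]]:
        return [b for b in (self.block, self.block2) if b]


@dataclass
class TrueHistory:
    root_genome: Genome
    events: dict[str, list[TrueEvent]]  # branch -> ordered events
    node_genomes: dict[str, Genome]  # every node incl. tips, pre-dropout
    retained: dict[str, set[str]]  # species -> markers kept after dropout
    origin: dict[str, str]  # marker -> root chromosome id

    def events_on_path(self, tree: Phylogeny, tip_a: str, tip_b: str) -> list[TrueEvent]:
        out = []
        for branch in tree.path_branches(tip_a, tip_b):
            out.extend(self.events.get(branch, []))
        return out


def simulate(params: SimulationParams) -> tuple[dict[str, GeneticMap], TrueHistory]:
    """Evolve a root genome down the tree; emit tip maps plus the truth."""
    rng = np.random.default_rng(params.seed)
    tree = params.tree

    root = [
        [f"c{c + 1:02d}m{m + 1:03d}" for m in range(params.markers_per_chromosome)]
        for c in range(params.chromosomes)
    ]
    origin = {
        marker: f"chr{c + 1}" for c, chrom in enumerate(root) for marker in chrom
    }

    events: dict[str, list[TrueEvent]] = {}
    node_genomes: dict[str, Genome] = {tree.root: [list(c) for c in root]}

    def descend(node: str) -> None:
        for child in tree.children(node):
            genome = [list(c) for c in node_genomes[node]]
            branch_events = _evolve_branch(
                genome, child, tree.branch_duration(child), params, rng
            )
            events[child] = branch_events
            node_genomes[child] = genome
            descend(child)

    descend(tree.root)

    maps: dict[str, GeneticMap] = {}
    retained: dict[str, set[str]] = {}
    for tip in tree.tips:
        genome = node_genomes[tip]
        if params.reference_full and tip == params.reference:
            keep = {m for chrom in genome for m in chrom}
        else:
            keep = {
                m
                for chrom in genome
                for m in chrom
                if rng.random() >= params.dropout
            }
        retained[tip] = keep
        loci = []
        for ci, chrom in enumerate(genome):
            pos = 0.0
            for marker in chrom:
                if marker not in keep:
                    continue
                pos += rng.uniform(1.0, 5.0)
                loci.append(MarkerLocus(marker, f"{tip}_chr{ci + 1}", round(pos, 3)))
        maps[tip] = GeneticMap(tip, loci)

    truth = TrueHistory(
        root_genome=root,
        events=events,
        node_genomes=node_genomes,
        retained=retained,
        origin=origin,
    )
    return maps, truth


def _evolve_branch(
    genome: Genome,
    branch: str,
    duration: float,
    params: SimulationParams,
    rng: np.random.Generator,
) -> list[TrueEvent]:
    n_inv = rng.poisson(params.inversion_rate * duration)
    n_tr = rng.poisson(params.translocation_rate * duration)
    kinds = [INVERSION] * n_inv + [TRANSLOCATION] * n_tr
    rng.shuffle(kinds)
    out = []
    for kind in kinds:
        if kind == INVERSION:
            out.append(_apply_inversion(genome, branch, params, rng))
        else:
            out.append(_apply_translocation(genome, branch, params, rng))
    return out


def _gap_weights(n_gaps: int, n_markers: int, params: SimulationParams) -> np.ndarray | None:
    if params.hotspots is None:
        return None
    w = np.ones(n_gaps)
    for frac in params.hotspots.positions:
        gap = int(round(frac * (n_markers)))
        gap = min(max(gap, 0), n_gaps - 1)
        w[gap] += params.hotspots.weight
    return w / w.sum()


def _draw_gap(rng: np.random.Generator, n_gaps: int, weights: np.ndarray | None) -> int:
    if weights is None:
        return int(rng.integers(0, n_gaps))
    return int(rng.choice(n_gaps, p=weights))


def _apply_inversion(
    genome: Genome, branch: str, params: SimulationParams, rng: np.random.Generator
) -> TrueEvent:
    for _ in range(1000):
        ci = int(rng.integers(0, len(genome)))
        chrom = genome[ci]
        n = len(chrom)
        if n < params.min_inversion_block:
            continue
        weights = _gap_weights(n + 1, n, params)
        g1 = _draw_gap(rng, n + 1, weights)
        g2 = _draw_gap(rng, n + 1, weights)
        lo, hi = min(g1, g2), max(g1, g2)
        if hi - lo < params.min_inversion_block:
            continue
        block = chrom[lo:hi]
        event = TrueEvent(
            kind=INVERSION,
            branch=branch,
            chromosome_index=ci,
            block=list(block),
            left_flank=chrom[lo - 1] if lo > 0 else None,
            right_flank=chrom[hi] if hi < n else None,
        )
        genome[ci] = chrom[:lo] + block[::-1] + chrom[hi:]
        return event
    raise RuntimeError("could not place inversion")  # pragma: no cover


def _apply_translocation(
    genome: Genome, branch: str, params: SimulationParams, rng: np.random.Generator
) -> TrueEvent:
    for _ in range(1000):
        if rng.random() < params.reciprocal_fraction:
            ev = _try_reciprocal(genome, branch, rng)
        else:
            ev = _try_insertional(genome, branch, rng)
        if ev is not None:
            return ev
    raise RuntimeError("could not place translocation")  # pragma: no cover


def _try_reciprocal(
    genome: Genome, branch: str, rng: np.random.Generator
) -> TrueEvent | None:
    ca, cb = rng.choice(len(genome), size=2, replace=False)
    a, b = genome[ca], genome[cb]
    if len(a) < 2 or len(b) < 2:
        return None
    ga = int(rng.integers(1, len(a)))
    gb = int(rng.integers(1, len(b)))
    new_a = a[:ga] + b[gb:]
    new_b = b[:gb] + a[ga:]
    if len(new_a) < 2 or len(new_b) < 2:
        return None
    event = TrueEvent(
        kind=TRANSLOCATION,
        branch=branch,
        chromosome_index=int(ca),
        block=a[ga:],
        left_flank=a[ga - 1],
        right_flank=None,
        detail="reciprocal",
        block2=b[gb:],
        chromosome_index2=int(cb),
    )
    genome[ca], genome[cb] = new_a, new_b
    return event


def _try_insertional(
    genome: Genome, branch: str, rng: np.random.Generator
) -> TrueEvent | None:
    cd, cr = rng.choice(len(genome), size=2, replace=False)
    donor = genome[cd]
    if len(donor) < 4:
        return None
    g1 = int(rng.integers(0, len(donor) - 1))
    g2 = int(rng.integers(g1 + 1, len(donor) + 1))
    segment = donor[g1:g2]
    rest = donor[:g1] + donor[g2:]
    if len(rest) < 2:
        return None
    recipient = genome[cr]
    gi = int(rng.integers(1, len(recipient)))  # internal: segment is embedded
    event = TrueEvent(
        kind=TRANSLOCATION,
        branch=branch,
        chromosome_index=int(cd),
        block=list(segment),
        left_flank=donor[g1 - 1] if g1 > 0 else None,
        right_flank=donor[g2] if g2 < len(donor) else None,
        detail="insertional",
        chromosome_index2=int(cr),
        insertion_index=gi,
    )
    genome[cd] = rest
    genome[cr] = recipient[:gi] + segment + recipient[gi:]
    return event


def replay(truth: TrueHistory, tree: Phylogeny) -> dict[str, Genome]:
    """Re-apply recorded events root -> tips; used to verify the history.

    Each event is replayed from its recorded block and flanks; the result
    must equal the recorded node genomes exactly, for every seed.
    """
    genomes = {tree.root: [list(c) for c in truth.root_genome]}

    def descend(node: str) -> None:
        for child in tree.children(node):
            genome = [list(c) for c in genomes[node]]
            for ev in truth.events.get(child, []):
                _replay_event(genome, ev)
            genomes[child] = genome
            descend(child)

    descend(tree.root)
    return genomes


def _replay_event(genome: Genome, ev: TrueEvent) -> None:
    if ev.kind == INVERSION:
        chrom = genome[ev.chromosome_index]
        lo = _block_start(chrom, ev.block)
        hi = lo + len(ev.block)
        genome[ev.chromosome_index] = chrom[:lo] + chrom[lo:hi][::-1] + chrom[hi:]
    elif ev.detail == "reciprocal":
        a = genome[ev.chromosome_index]
        b = genome[ev.chromosome_index2]
        ga = _block_start(a, ev.block)
        gb = _block_start(b, ev.block2)
        genome[ev.chromosome_index] = a[:ga] + b[gb:]
        genome[ev.chromosome_index2] = b[:gb] + a[ga:]
    else:  # insertional
        donor = genome[ev.chromosome_index]
        lo = _block_start(donor, ev.block)
        hi = lo + len(ev.block)
        genome[ev.chromosome_index] = donor[:lo] + donor[hi:]
        recipient = genome[ev.chromosome_index2]
        gi = ev.insertion_index
        genome[ev.chromosome_index2] = recipient[:gi] + ev.block + recipient[gi:]


def _block_start(chrom: list[str], block: list[str]) -> int:
    first = block[0]
    idx = chrom.index(first)
    if chrom[idx : idx + len(block)] != block:
        raise AssertionError("recorded block not contiguous at replay")
    return idx


# ---------------------------------------------------------------------------
# Bundled observation fixture
# ---------------------------------------------------------------------------

FIXTURE_FILES = [
    "solanaceae_observations.tsv",
    "solanaceae_reference_map.tsv",
    "solanaceae_centromeres.tsv",
    "solanaceae_tree.nwk",
    "solanaceae_config.yaml",
]


def fixture_path(name: str) -> Path:
    """Path of a bundled Solanaceae fixture file."""
    ref = resources.files("synkaryo.data").joinpath(name)
    return Path(str(ref))


def make_paper_fixture(out_dir: str | Path) -> list[Path]:
    """Write the bundled multi-species Solanaceae observation set.

    One row per rearrangement event with its per-species presence pattern,
    plus the reference marker scaffold, centromere table and dated tree
    the observations are expressed against.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES:
        dest = out_dir / name
        shutil.copyfile(fixture_path(name), dest)
        written.append(dest)
    return written


def identity_orthology(maps: dict[str, GeneticMap]) -> OrthologyTable:
    return OrthologyTable.identity(maps.values())
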