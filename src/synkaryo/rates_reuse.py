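"""Per-branch rearrangement rates and breakpoint-reuse detection.

Rates are counts over branch durations (MY).  Undetermined events give a
count range [min, max]: the minimum excludes them, the maximum charges
every branch in the candidate set.  Printed rates round half away from
zero to one decimal; per-chromosome rates divide by the (constant)
chromosome number.

Breakpoint reuse: independent translocation junctions from different
species whose breakpoint intervals intersect on the reference rank axis
are grouped (transitive closure over pairwise intersection); the shared
region narrows to the common overlap, and its distance to the reference
centromere interval decides centromere proximity.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .map_model_io import Phylogeny
from .timing_parsimony import CountTable, EventObservation

DEFAULT_CHROMOSOME_NUMBER = 12
DEFAULT_PROXIMITY_WINDOW = 1


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (matches printed one-decimal rates)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class RateEstimate:
    branch: str
    kind: str
    count_min: int
    count_max: int
    branch_duration: float
    chromosome_number: int = DEFAULT_CHROMOSOME_NUMBER

    def __post_init__(self) -> None:
        if self.branch_duration <= 0:
            raise ValueError(f"branch {self.branch}: non-positive duration")
        if self.count_min > self.count_max:
            raise ValueError(f"branch {self.branch}: count_min > count_max")

    @property
    def rate_min(self) -> float:
        return self.count_min / self.branch_duration

    @property
    def rate_max(self) -> float:
        return self.count_max / self.branch_duration

    @property
    def rate_min_rounded(self) -> float:
        return round_half_away(self.rate_min)

    @property
    def rate_max_rounded(self) -> float:
        return round_half_away(self.rate_max)

    @property
    def per_chromosome_rate(self) -> tuple[float, float]:
        return (
            self.rate_min / self.chromosome_number,
            self.rate_max / self.chromosome_number,
        )


def estimate_rates(
    count_table: CountTable,
    tree: Phylogeny,
    chromosome_number: int = DEFAULT_CHROMOSOME_NUMBER,
) -> list[RateEstimate]:
    """Turn a per-branch count table into rate estimates with ranges."""
    out = []
    for (branch, kind), bc in sorted(count_table.counts.items()):
        duration = tree.branch_duration(branch)
        out.append(
            RateEstimate(
                branch=branch,
                kind=kind,
                count_min=bc.count_min,
                count_max=bc.count_max,
                branch_duration=duration,
                chromosome_number=chromosome_number,
            )
        )
    return out


def write_rates(rates: Iterable[RateEstimate], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["branch", "kind", "count_min", "count_max", "duration_MY",
             "rate_min", "rate_max", "rate_min_rounded", "rate_max_rounded",
             "per_chromosome_min", "per_chromosome_max"]
        )
        for r in rates:
            pc_min, pc_max = r.per_chromosome_rate
            writer.writerow(
                [r.branch, r.kind, r.count_min, r.count_max,
                 f"{r.branch_duration:g}",
                 f"{r.rate_min:.4f}", f"{r.rate_max:.4f}",
                 f"{r.rate_min_rounded:g}", f"{r.rate_max_rounded:g}",
                 f"{pc_min:.4f}", f"{pc_max:.4f}"]
            )


# ---------------------------------------------------------------------------
# Breakpoint reuse
# ---------------------------------------------------------------------------


@dataclass
class ReuseGroup:
    ref_chromosome: str
    members: list[EventObservation]
    narrowed: tuple[int, int] | None
    centromere_proximal: bool = False

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for m in self.members for s in m.carriers)


def _gaps(interval: tuple[int, int]) -> set[int]:
    """Marker gaps covered by an open rank interval (gap g = between g, g+1)."""
    lo, hi = interval
    return set(range(lo, hi))


def _gap_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    ga, gb = _gaps(a), _gaps(b)
    if ga & gb:
        return 0
    return min(abs(x - y) for x in ga for y in gb)


def detect_breakpoint_reuse(
    events: Sequence[EventObservation],
    centromere_flanks: Mapping[str, tuple[int, int]] | None = None,
    proximity_window: int = DEFAULT_PROXIMITY_WINDOW,
) -> list[ReuseGroup]:
    """Group independent translocations with intersecting breakpoints.

    ``events`` are translocation observations whose ``span`` is the
    breakpoint rank interval on the reference and whose carriers identify
    the species the junction was observed in.  A group needs members from
    at least two species: two junctions seen in one species are one
    lineage's history, not evidence of reuse.  Output order is by
    reference chromosome then narrowed interval, independent of input
    order.  ``centromere_flanks`` maps reference chromosome -> centromere
    flanking rank interval; a group is centromere-proximal when its
    narrowed region lies within ``proximity_window`` marker intervals of it.
    """
    by_chrom: dict[str, list[EventObservation]] = {}
    for ev in events:
        by_chrom.setdefault(ev.ref_chromosome, []).append(ev)

    groups: list[ReuseGroup] = []
    for chrom in sorted(by_chrom):
        chrom_events = sorted(by_chrom[chrom], key=lambda e: (e.span, e.event_id))
        parent = list(range(len(chrom_events)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(chrom_events)):
            for j in range(i + 1, len(chrom_events)):
                a, b = chrom_events[i].span, chrom_events[j].span
                if max(a[0], b[0]) < min(a[1], b[1]):
                    parent[find(i)] = find(j)

        clusters: dict[int, list[EventObservation]] = {}
        for i, ev in enumerate(chrom_events):
            clusters.setdefault(find(i), []).append(ev)

        for members in clusters.values():
            if len(members) < 2:
                continue
            species = {s for m in members for s in m.carriers}
            if len(species) < 2:
                continue
            lo = max(m.span[0] for m in members)
            hi = min(m.span[1] for m in members)
            narrowed = (lo, hi) if lo < hi else None
            group = ReuseGroup(chrom, members, narrowed)
            if centromere_flanks and chrom in centromere_flanks:
                region = narrowed if narrowed else (
                    min(m.span[0] for m in members), max(m.span[1] for m in members)
                )
                group.centromere_proximal = (
                    _gap_distance(region, centromere_flanks[chrom])
                    <= proximity_window
                )
            groups.append(group)
    groups.sort(key=lambda g: (g.ref_chromosome, g.narrowed or (0, 0)))
    return groups


def write_reuse(groups: Iterable[ReuseGroup], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["ref_chromosome", "n_members", "species", "member_events",
             "narrowed_lo", "narrowed_hi", "centromere_proximal"]
        )
        for g in groups:
            lo, hi = g.narrowed if g.narrowed else ("", "")
            writer.writerow(
                [g.ref_chromosome, len(g.members),
                 ";".join(sorted(g.species)),
                 ";".join(m.event_id for m in g.members),
                 lo, hi, str(g.centromere_proximal).lower()]
            )


def expected_gap_collisions(n_events: int, n_gaps: int) -> float:
    """Closed-form expected number of gaps hit by >=2 of ``n_events``
    uniform independent breakpoints (birthday-problem benchmark for the
    simulator's uniform breakage model)."""
    if n_gaps <= 0:
        raise ValueError("n_gaps must be positive")
    p0 = (1 - 1 / n_gaps) ** n_events
    p1 = n_events / n_gaps * (1 - 1 / n_gaps) ** (n_events - 1)
    return n_gaps * (1 - p0 - p1)
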