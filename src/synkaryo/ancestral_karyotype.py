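"""Reconstruct ancestral karyotypes chromosome by chromosome.

A node's genome sits at the *bottom* of its branch, so events assigned to
the branches of its two children are exactly the events separating the
node from its daughter lineages.  Per chromosome:

* no child-branch events           -> resolved, both daughters preserve it;
* events on one child branch only  -> resolved, the other daughter is the
                                      representative (polarity was fixed by
                                      an outgroup when the event was timed);
* events on both child branches    -> the ancestor matches neither daughter
                                      verbatim: partially resolved;
* an *undetermined* event whose candidate branches fall on both sides of
  the node's comparison makes the outcome undecidable: translocation ->
  karyotype unknown; inversion -> partially resolved (gene order hedged).

Unknown status propagates rootward: reconstruct tipward nodes first.
The basal-most node cannot be reconstructed at all (no outgroup fixes
polarity) and is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .map_model_io import Phylogeny
from .timing_parsimony import INVERSION, TRANSLOCATION, LineageAssignment

RESOLVED = "resolved"
PARTIALLY_RESOLVED = "partially_resolved"
UNKNOWN = "unknown"

BOTH = "both"


class ReconstructionError(ValueError):
    """Raised when a node has no outgroup to polarise the comparison."""


@dataclass
class AncestralChromosome:
    ancestor: str
    chromosome: str
    status: str
    representative: str | None  # child node id, BOTH, or None
    gene_order_representative: str | None = None
    rationale: str = ""
    derived_events: dict[str, int] = field(default_factory=dict)  # child -> n events

    @property
    def resolved(self) -> bool:
        return self.status == RESOLVED


@dataclass
class AncestralKaryotype:
    node: str
    chromosomes: dict[str, AncestralChromosome]

    def status_of(self, chromosome: str) -> str:
        return self.chromosomes[chromosome].status

    def by_status(self, status: str) -> list[str]:
        return [c for c, a in self.chromosomes.items() if a.status == status]


def _subtree_branches(tree: Phylogeny, node: str) -> frozenset[str]:
    """The branch to ``node`` plus every branch below it."""
    below = tree.tipset(node)
    return frozenset(
        b for b in tree.branches if tree.tipset(b) <= below
    )


def reconstruct_node(
    node: str,
    tree: Phylogeny,
    assignments: Iterable[LineageAssignment],
    chromosome_ids: Sequence[str],
    child_karyotypes: dict[str, "AncestralKaryotype"] | None = None,
) -> AncestralKaryotype:
    """Reconstruct one internal node from timed events.

    ``child_karyotypes`` supplies already-reconstructed internal children
    so that their unknown chromosomes propagate rootward.  The root (no
    outgroup beyond it) is refused: deciding which daughter preserves the
    ancestral arrangement needs at least one more-distant species.
    """
    if node == tree.root:
        raise ReconstructionError(
            f"{node}: reconstruction requires a more distant species to "
            "polarise the root comparison"
        )
    children = tree.children(node)
    if len(children) != 2:
        raise ReconstructionError(f"{node}: not an internal binary node")
    child_karyotypes = child_karyotypes or {}
    sides = {c: _subtree_branches(tree, c) for c in children}
    assignments = list(assignments)

    chromosomes: dict[str, AncestralChromosome] = {}
    for chrom in chromosome_ids:
        on_chrom = [a for a in assignments if a.ref_chromosome == chrom]

        inherited_unknown = any(
            child_karyotypes[c].status_of(chrom) == UNKNOWN
            for c in children
            if c in child_karyotypes and chrom in child_karyotypes[c].chromosomes
        )

        ambiguous_tr = [
            a for a in on_chrom
            if not a.determined and a.kind == TRANSLOCATION
            and all(a.candidate_set & sides[c] for c in children)
        ]
        ambiguous_inv = [
            a for a in on_chrom
            if not a.determined and a.kind == INVERSION
            and all(a.candidate_set & sides[c] for c in children)
        ]
        derived = {
            c: sum(a.min_count for a in on_chrom if a.determined and a.branch == c)
            for c in children
        }

        inv_derived = {
            c: sum(
                a.min_count
                for a in on_chrom
                if a.determined and a.branch == c and a.kind == INVERSION
            )
            for c in children
        }
        gene_order_rep = _pick_representative(inv_derived, children)

        if inherited_unknown or ambiguous_tr:
            rationale = (
                "unknown karyotype inherited from daughter node"
                if inherited_unknown
                else "translocation timing undetermined between the compared lineages"
            )
            chromosomes[chrom] = AncestralChromosome(
                node, chrom, UNKNOWN, representative=None,
                gene_order_representative=gene_order_rep,
                rationale=rationale, derived_events=derived,
            )
            continue

        representative = _pick_representative(derived, children)
        if ambiguous_inv:
            chromosomes[chrom] = AncestralChromosome(
                node, chrom, PARTIALLY_RESOLVED, representative=representative,
                gene_order_representative=gene_order_rep,
                rationale="inversion timing undetermined between the compared lineages",
                derived_events=derived,
            )
        elif representative is None:
            chromosomes[chrom] = AncestralChromosome(
                node, chrom, PARTIALLY_RESOLVED, representative=None,
                gene_order_representative=gene_order_rep,
                rationale="both daughter lineages carry derived events",
                derived_events=derived,
            )
        else:
            chromosomes[chrom] = AncestralChromosome(
                node, chrom, RESOLVED, representative=representative,
                gene_order_representative=gene_order_rep,
                derived_events=derived,
            )
    return AncestralKaryotype(node, chromosomes)


def _pick_representative(
    derived: dict[str, int], children: list[str]
) -> str | None:
    clean = [c for c in children if derived.get(c, 0) == 0]
    if len(clean) == 2:
        return BOTH
    if len(clean) == 1:
        return clean[0]
    return None


def reconstruct_all(
    tree: Phylogeny,
    assignments: Iterable[LineageAssignment],
    chromosome_ids: Sequence[str],
) -> dict[str, AncestralKaryotype]:
    """Reconstruct every reconstructable internal node, tipward first."""
    assignments = list(assignments)
    internal = [
        n for n in tree.branches
        if not tree.is_tip(n)
    ]
    internal.sort(key=lambda n: tree.node_ages[n])  # youngest (tipward) first
    done: dict[str, AncestralKaryotype] = {}
    for node in internal:
        done[node] = reconstruct_node(
            node, tree, assignments, chromosome_ids, child_karyotypes=done
        )
    return done


def extant_representative(
    node: str,
    karyotypes: dict[str, AncestralKaryotype],
    chromosome: str,
    tree: Phylogeny,
) -> str | None:
    """Follow representatives tipward to an extant species, if resolvable."""
    current = node
    while True:
        if tree.is_tip(current):
            return current
        k = karyotypes.get(current)
        if k is None or chromosome not in k.chromosomes:
            return None
        rep = k.chromosomes[chromosome].representative
        if rep is None:
            return None
        if rep == BOTH:
            rep = tree.children(current)[0]
        current = rep


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_STATUS_GLYPH = {RESOLVED: "=", PARTIALLY_RESOLVED: "~", UNKNOWN: "/"}


def render_karyotype(
    karyotype: AncestralKaryotype,
    painting: dict[str, list[str]] | None = None,
) -> str:
    """Plain-text karyotype report: one bar per chromosome.

    ``painting`` optionally lists, per chromosome, the reference
    chromosomes contributing segments; a single entry renders as a
    single-colour bar.  Unknown chromosomes render as broken bars.
    """
    lines = [f"# {karyotype.node}"]
    for chrom, anc in karyotype.chromosomes.items():
        paint = (painting or {}).get(chrom, [chrom])
        glyph = _STATUS_GLYPH[anc.status]
        if anc.status == UNKNOWN:
            bar = " // ".join(f"[{p}]" for p in paint)
        else:
            bar = "[" + (glyph * 2).join(paint) + "]"
        rep = anc.representative or "-"
        lines.append(
            f"{karyotype.node}{chrom.lstrip('T') if chrom.startswith('T') else chrom}"
            f"\t{anc.status}\t{rep}\t{bar}"
        )
    return "\n".join(lines) + "\n"


def render_karyotype_svg(
    karyotype: AncestralKaryotype,
    painting: dict[str, list[str]] | None = None,
    bar_width: int = 22,
    bar_height: int = 120,
) -> str:
    """Minimal standalone SVG: one bar per chromosome, broken when unknown."""
    palette = [
        "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231", "#911eb4",
        "#46f0f0", "#f032e6", "#bcf60c", "#fabebe", "#008080", "#e6beff",
    ]
    chroms = list(karyotype.chromosomes)
    color_of = {c: palette[i % len(palette)] for i, c in enumerate(chroms)}
    parts = []
    gap = 14
    for i, chrom in enumerate(chroms):
        anc = karyotype.chromosomes[chrom]
        x = 10 + i * (bar_width + gap)
        paint = (painting or {}).get(chrom, [chrom])
        n = len(paint)
        seg_h = bar_height // max(n, 1)
        y = 20
        for j, ref in enumerate(paint):
            fill = color_of.get(ref, "#999999")
            broken_gap = 6 if anc.status == UNKNOWN and j > 0 else 0
            y += broken_gap
            parts.append(
                f'<rect x="{x}" y="{y}" width="{bar_width}" height="{seg_h - broken_gap}" '
                f'rx="6" fill="{fill}" stroke="#333"/>'
            )
            y += seg_h - broken_gap
        parts.append(
            f'<text x="{x + bar_width / 2}" y="{bar_height + 38}" font-size="9" '
            f'text-anchor="middle">{chrom}</text>'
        )
    width = 20 + len(chroms) * (bar_width + gap)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{bar_height + 50}">'
        f'<text x="10" y="14" font-size="12">{karyotype.node}</text>'
        + "".join(parts)
        + "</svg>"
    )
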