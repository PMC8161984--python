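"""Node-based small-variant detection on the cSupB tree.

The working assumption is that every variant corresponds one-to-one to a
cSupB source node.  Final offsets (reverse traversal + subtraction) place
indel length jumps on the edges leaving a source node, so each source carries
per-branch gap information: gap(branch) = final(first node of branch) -
final(source) - 1.  Typing follows the nested variant detection (NVD) rules:

* both branch gaps zero            -> substitution        (vartype 1)
* gap on the reference branch > 0  -> insertion in the alternates (vartype 3)
* gap on an alternate branch > 0   -> deletion in that alternate  (vartype 2)
* irreducible ambiguity            -> indel, unsure 2 or 3 (vartype 4)

Nested configurations are resolved jointly: the length imbalance already
introduced by descendant source nodes inside a branch is discounted before
typing the parent (otherwise an insertion below a substitution masquerades as
an insertion at the substitution's source).  Source nodes in cSupBs that do
not contain the reference are typed afterwards through the nearest
reference-containing ancestor (the parent-to-child FCVD ordering).

Reference position determination (RPD) anchors every source node to a
1-based reference coordinate — exactly for nodes on the reference path,
approximately (ancestor offset propagation corrected by branch gaps) for the
rest — after which node variants become locus variants with VCF alleles.
Only small indels (< 50 bp) are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .decompose import CSupBTree
from .graph import ColoredDBG, ColorSet, Genome
from .traversal import OffsetMap

__all__ = [
    "GapInfo",
    "NodeVariant",
    "LocusVariant",
    "collect_gaps",
    "nvd_reference_pass",
    "nvd_nonreference_pass",
    "rpd",
    "node_to_locus",
    "call_variants",
    "MAX_INDEL",
]

MAX_INDEL = 50   # indels of this length or longer are out of scope

SUB, DEL, INS, UNSURE = 1, 2, 3, 4


@dataclass
class GapInfo:
    """Per-branch final-offset gaps at one source node."""

    source: str
    branches: list[tuple[int, int, str]]   # (edge color, gap, first node)
    max_gap: int
    max_gap_color: int

    def gap_of(self, head: str) -> int:
        for col, gap, h in self.branches:
            if h == head:
                return gap
        raise KeyError(head)


@dataclass
class NodeVariant:
    source: str
    vartype: int                   # 1 sub | 2 del | 3 ins | 4 unsure
    affected_color: int            # samples carrying the non-reference state
    branch_head: str               # first node of the affected branch
    length: int = 0                # indel length (0 for substitutions)


@dataclass
class LocusVariant:
    refpos: int                    # 1-based on the designated reference
    ref_allele: str
    alt_allele: str
    vartype: int
    affected_color: int
    n_samples: int = 0

    @property
    def colorset(self) -> ColorSet:
        return ColorSet(self.affected_color, self.n_samples)


# ---------------------------------------------------------------------------
# gap collection
# ---------------------------------------------------------------------------

def source_nodes(graph: ColoredDBG, tree: CSupBTree) -> list[str]:
    """Distinct cSupB source nodes, ordered by the smallest cSupB order in
    which each appears (the NVD small-to-large traversal order)."""
    seen: dict[str, int] = {}
    for o in sorted(tree.bubbles):
        s = tree[o].source
        seen.setdefault(s, o)
    return sorted(seen, key=lambda s: seen[s])


def deepest_bubble_at(tree: CSupBTree, source: str):
    """The smallest (deepest) cSupB whose source is the given node."""
    best = None
    for b in tree:
        if b.source == source and (best is None or len(b.nodes) < len(best.nodes)):
            best = b
    return best


def collect_gaps(
    graph: ColoredDBG, offsets: OffsetMap, tree: CSupBTree
) -> dict[str, GapInfo]:
    """Final-offset gap of every out-branch of every cSupB source node.

    Substitution branches carry gap 0; an indel of length L puts a gap of L
    on the short branch's edge out of the source.
    """
    final = offsets.final
    out: dict[str, GapInfo] = {}
    for s in source_nodes(graph, tree):
        branches = []
        for head, ecol in graph.successors(s).items():
            gap = final[head] - final[s] - 1
            branches.append((ecol, gap, head))
        max_col, max_gap, _ = max(branches, key=lambda b: b[1])
        out[s] = GapInfo(
            source=s, branches=branches, max_gap=max_gap, max_gap_color=max_col
        )
    return out


# ---------------------------------------------------------------------------
# nested gap discounting
# ---------------------------------------------------------------------------

def _branch_region(graph: ColoredDBG, head: str, sink: str, nodes: frozenset) -> set:
    """Nodes reachable from a branch head inside a bubble without passing the
    sink (the branch side of the bubble)."""
    seen = {head}
    stack = [head]
    while stack:
        u = stack.pop()
        if u == sink:
            continue
        for v in graph.successors(u):
            if v in nodes and v != sink and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _descendant_delta(
    graph: ColoredDBG,
    tree: CSupBTree,
    gaps: dict[str, GapInfo],
    region: set,
    exclude: str,
    memo: dict[str, int],
) -> int:
    """Summed net length imbalance introduced by source nodes inside a branch
    region (each source's own imbalance after discounting its descendants)."""
    total = 0
    for d in region:
        if d == exclude or d not in gaps:
            continue
        total += _net_delta(graph, tree, gaps, d, memo)
    return total


def _net_delta(graph, tree, gaps, d, memo) -> int:
    if d in memo:
        return memo[d]
    memo[d] = 0   # break potential self-reference
    gi = gaps[d]
    bub = deepest_bubble_at(tree, d)
    raw = gi.max_gap
    if bub is not None and raw > 0:
        # discount descendants inside the long branch
        long_heads = [h for c, g, h in gi.branches if g == 0]
        inner = 0
        for h in long_heads:
            region = _branch_region(graph, h, bub.sink, bub.nodes) - {h}
            inner = max(
                inner,
                _descendant_delta(graph, tree, gaps, region, d, memo),
            )
        raw = max(raw - inner, 0)
    memo[d] = raw
    return raw


# ---------------------------------------------------------------------------
# NVD pass 1 — cSupBs containing the reference
# ---------------------------------------------------------------------------

def nvd_reference_pass(
    graph: ColoredDBG,
    tree: CSupBTree,
    gaps: dict[str, GapInfo],
    ref_idx: int,
) -> tuple[list[NodeVariant], dict[str, int]]:
    """Type every source node lying on the reference path, smallest cSupB id
    first.  Returns the node variants plus insertion hints consumed from
    descendant sources (used to orient the non-reference pass)."""
    ref_bit = 1 << ref_idx
    memo: dict[str, int] = {}
    hints: dict[str, int] = {}
    variants: list[NodeVariant] = []
    for s in source_nodes(graph, tree):
        if not graph.nodes[s] & ref_bit:
            continue
        gi = gaps[s]
        ref_branches = [b for b in gi.branches if b[0] & ref_bit]
        if len(ref_branches) != 1:
            continue   # reference path forks here only via anchoring defects
        rcol, rgap, rhead = ref_branches[0]
        bub = deepest_bubble_at(tree, s)
        for acol, agap, ahead in gi.branches:
            if ahead == rhead:
                continue
            delta = rgap - agap    # >0: alternate branch longer than reference
            if delta > 0 and bub is not None:
                region = _branch_region(graph, ahead, bub.sink, bub.nodes)
                cap = _descendant_delta(graph, tree, gaps, region, s, memo)
                absorbed = min(delta, cap)
                if absorbed:
                    for d in region:
                        if d in gaps and d != s and _net_delta(graph, tree, gaps, d, memo) > 0:
                            hints[d] = INS
                delta -= absorbed
            elif delta < 0 and bub is not None:
                region = _branch_region(graph, rhead, bub.sink, bub.nodes)
                cap = _descendant_delta(graph, tree, gaps, region, s, memo)
                delta += min(-delta, cap)
            if delta == 0:
                variants.append(NodeVariant(s, SUB, acol, ahead, 0))
            elif delta > 0:
                variants.append(NodeVariant(s, INS, acol, ahead, delta))
            else:
                variants.append(NodeVariant(s, DEL, acol, ahead, -delta))
    return variants, hints


# ---------------------------------------------------------------------------
# NVD pass 2 — cSupBs without the reference (FCVD ordering)
# ---------------------------------------------------------------------------

def nvd_nonreference_pass(
    graph: ColoredDBG,
    tree: CSupBTree,
    gaps: dict[str, GapInfo],
    ref_idx: int,
    hints: Optional[dict[str, int]] = None,
) -> list[NodeVariant]:
    """Type the remaining source nodes (cSupBs lacking the reference),
    again from small to large cSupB id, using the insertion orientation
    inherited from the reference pass where available."""
    ref_bit = 1 << ref_idx
    hints = hints or {}
    variants: list[NodeVariant] = []
    memo: dict[str, int] = {}
    for s in source_nodes(graph, tree):
        if graph.nodes[s] & ref_bit:
            continue
        gi = gaps[s]
        has_ancestor = _has_ref_ancestor(tree, s, ref_bit)
        # pair every branch against the longest (gap-0) branch
        long_col, long_gap, long_head = min(gi.branches, key=lambda b: b[1])
        for acol, agap, ahead in gi.branches:
            delta = agap - long_gap   # >0: this branch shorter by delta
            if delta == 0:
                # substitution candidate; the locus transformation drops the
                # branch matching the reference base at the mapped position
                variants.append(NodeVariant(s, SUB, acol, ahead, 0))
            elif hints.get(s) == INS:
                variants.append(NodeVariant(s, INS, long_col, long_head, delta))
            else:
                if not has_ancestor:
                    warnings.warn(
                        f"source {s} has no reference-containing ancestor; "
                        "typing its indel as unsure",
                        stacklevel=2,
                    )
                variants.append(
                    NodeVariant(s, UNSURE, acol | long_col, long_head, delta)
                )
    # deduplicate substitution pairs emitted twice at multi-branch sources
    seen = set()
    out = []
    for v in variants:
        key = (v.source, v.vartype, v.branch_head, v.affected_color)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def _has_ref_ancestor(tree: CSupBTree, source: str, ref_bit: int) -> bool:
    b = deepest_bubble_at(tree, source)
    while b is not None:
        if b.color & ref_bit:
            return True
        b = tree[b.parent] if b.parent is not None else None
    return False


# ---------------------------------------------------------------------------
# reference position determination
# ---------------------------------------------------------------------------

def rpd(
    graph: ColoredDBG,
    tree: CSupBTree,
    offsets: OffsetMap,
    ref_id: str,
    gaps: Optional[dict[str, GapInfo]] = None,
) -> dict[str, int]:
    """Node -> 1-based reference position of the k-mer's last base.

    Exact for nodes on the reference path (position = path index, anchors
    occupying indices 0 and beyond the sequence length); approximate for
    other source nodes, which inherit from the nearest reference-containing
    ancestor source adjusted by final-offset differences and the entry
    branch's gap.
    """
    final = offsets.final
    refmap: dict[str, int] = {}
    ref_path = graph.sample_paths[ref_id]
    for i, node in enumerate(ref_path):
        refmap[node] = i
    ref_idx = graph.sample_ids.index(ref_id)
    ref_bit = 1 << ref_idx
    if gaps is None:
        gaps = collect_gaps(graph, offsets, tree)
    for s in source_nodes(graph, tree):
        if s in refmap:
            continue
        anc = _nearest_ref_source(graph, tree, s, ref_bit)
        if anc is None:
            continue
        entry_gap = 0
        bub = deepest_bubble_at(tree, anc)
        if bub is not None and anc in gaps:
            for col, gap, head in gaps[anc].branches:
                region = _branch_region(graph, head, bub.sink, bub.nodes)
                if s in region:
                    entry_gap = gap
                    break
        refmap[s] = refmap[anc] + (final[s] - final[anc]) - entry_gap
    return refmap


def _nearest_ref_source(graph, tree, source, ref_bit) -> Optional[str]:
    b = deepest_bubble_at(tree, source)
    while b is not None:
        if graph.nodes[b.source] & ref_bit:
            return b.source
        b = tree[b.parent] if b.parent is not None else None
    return None


# ---------------------------------------------------------------------------
# node variant -> locus variant
# ---------------------------------------------------------------------------

def node_to_locus(
    graph: ColoredDBG,
    node_variants: Sequence[NodeVariant],
    refmap: dict[str, int],
    reference: Genome,
    ref_idx: int,
) -> list[LocusVariant]:
    """Spell VCF-style left-anchored alleles for each node variant.

    Substitution branches whose base equals the reference base at the mapped
    position describe the reference state, not a variant, and are dropped;
    indel alleles of MAX_INDEL bases or more are skipped with a warning.
    """
    ref_seq = reference.sequence
    ref_bit = 1 << ref_idx
    out: list[LocusVariant] = []
    seen: set[tuple] = set()
    for nv in node_variants:
        p0 = refmap.get(nv.source)
        if p0 is None:
            continue
        color = nv.affected_color & ~ref_bit
        if color == 0:
            continue
        if nv.vartype == SUB:
            pos = p0 + 1
            if not 1 <= pos <= len(ref_seq):
                continue
            alt = nv.branch_head[-1]
            ref_base = ref_seq[pos - 1]
            if alt == ref_base:
                continue
            rec = LocusVariant(pos, ref_base, alt, SUB, color, graph.n_samples)
        else:
            L = nv.length
            if L >= MAX_INDEL:
                warnings.warn(
                    f"indel of length {L} at source {nv.source} exceeds the "
                    f"small-indel scope (<{MAX_INDEL} bp); skipped",
                    stacklevel=2,
                )
                continue
            if not 1 <= p0 <= len(ref_seq):
                continue
            anchor = ref_seq[p0 - 1]
            if nv.vartype == DEL:
                if p0 + L > len(ref_seq):
                    continue
                rec = LocusVariant(
                    p0, ref_seq[p0 - 1 : p0 + L], anchor, DEL, color, graph.n_samples
                )
            else:   # INS or UNSURE: spell inserted bases from an affected path
                ins = _spell_branch(graph, nv, L)
                if ins is None:
                    continue
                rec = LocusVariant(
                    p0, anchor, anchor + ins, nv.vartype, color, graph.n_samples
                )
        key = (rec.refpos, rec.ref_allele, rec.alt_allele, rec.affected_color)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    out.sort(key=lambda v: (v.refpos, v.alt_allele))
    return out


def _spell_branch(graph: ColoredDBG, nv: NodeVariant, L: int) -> Optional[str]:
    for i in range(graph.n_samples):
        if nv.affected_color >> i & 1:
            path = graph.sample_paths[graph.sample_ids[i]]
            try:
                j = path.index(nv.source)
            except ValueError:
                continue
            seg = path[j + 1 : j + 1 + L]
            if len(seg) == L:
                return "".join(n[-1] for n in seg)
    return None


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def call_variants(
    graph: ColoredDBG,
    tree: CSupBTree,
    offsets: OffsetMap,
    genomes: Sequence[Genome],
    ref_id: str,
) -> tuple[list[NodeVariant], list[LocusVariant]]:
    """Gap collection -> NVD passes 1-2 -> RPD -> locus transformation."""
    ref_idx = graph.sample_ids.index(ref_id)
    gaps = collect_gaps(graph, offsets, tree)
    nv1, hints = nvd_reference_pass(graph, tree, gaps, ref_idx)
    nv2 = nvd_nonreference_pass(graph, tree, gaps, ref_idx, hints)
    node_variants = nv1 + nv2
    refmap = rpd(graph, tree, offsets, ref_id, gaps)
    reference = next(g for g in genomes if g.sample_id == ref_id)
    locus = node_to_locus(graph, node_variants, refmap, reference, ref_idx)
    return node_variants, locus
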