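"""Cycle identification, interval location, cutting-point scoring and
sequence cutting for cyclic colored de Bruijn graphs.

A k value at or below the longest repeat segment length leaves directed
cycles in the graph (single-sample repeats, or repeats shared across
samples).  The postorder-like traversal then finishes in advance and leaves
half-visited nodes, at least one of which lies on a cycle.  The cycle's
offset interval is located by forcing the minimal-offset half-visited node
fully visited and resuming until one of its adjacent parents is visited.  A
cutting point inside the interval is chosen by the score R = L/t (run length
of positions with identical information over thickness), preferring bridges;
each sample is then cut at its own occurrence of the chosen segment,
re-anchored, and the per-segment graphs rebuilt acyclically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .graph import ColoredDBG, Genome, build_graph
from .traversal import _State, VisitState, postorder_traverse

__all__ = [
    "CycleRecord",
    "CutRegion",
    "detect_cycles",
    "locate_cycle_intervals",
    "score_cut_regions",
    "cut_and_rebuild",
]


@dataclass
class CycleRecord:
    cycle_start_node: str
    cycle_end_node: str
    cycle_start_pos: int
    cycle_end_pos: int
    half_visited: list[tuple[str, str]] = field(default_factory=list)
    # (node, "on_cycle" | "off_cycle") at the stall that revealed this cycle

    @property
    def interval(self) -> tuple[int, int]:
        return (self.cycle_start_pos, self.cycle_end_pos)


@dataclass
class CutRegion:
    interval: tuple[int, int]       # offset run covered by the region
    point_type: str                 # "I" bridge | "II" all samples | "III" partial
    L: int                          # run length of same-information loci
    t: int                          # thickness
    bases: str                      # per-offset consensus across the region
    reference_cut_pos: int          # middle offset of the region
    segment: str = ""               # searchable cut segment (a k-mer ending
                                    # at reference_cut_pos)
    segment_color: int = 0          # samples guaranteed to contain it

    @property
    def R(self) -> float:
        return self.L / self.t if self.t else 0.0


def detect_cycles(graph: ColoredDBG) -> list[str]:
    """Half-visited node set of the stalled forward traversal; empty iff the
    graph is acyclic."""
    res = postorder_traverse(graph, "forward")
    return res.half_visited if res.early_finish else []


def locate_cycle_intervals(graph: ColoredDBG) -> list[CycleRecord]:
    """Steps 1-4 of cycle interval determination.

    While the forward traversal is stalled: take the half-visited node u with
    minimal (tentative) offset, mark it fully visited at that offset, and
    resume.  When a node v adjacent-parent of u is later visited the cycle
    interval [pos(u), pos(v)] is recorded; if the traversal stalls again
    without closing, the new half-visited set reveals either the next cycle or
    an off-cycle candidate, and the steps repeat.  Termination is guaranteed
    because every iteration forces at least one node.
    """
    st = _State(graph, "forward")
    records: list[CycleRecord] = []
    forced: dict[str, dict] = {}     # forced node -> closure bookkeeping

    def on_visit(v: str) -> None:
        for w in graph.successors(v):
            if w in forced and forced[w]["record"] is None:
                info = forced[w]
                if info["best"] is None or st.offsets[v] > info["best"][1]:
                    info["best"] = (v, st.offsets[v])

    st.run(on_visit)
    while st.early_finish:
        half = st.half_visited
        if not half:
            # stalled without half-visited nodes cannot happen on a connected
            # anchored graph; bail out defensively
            break
        half_info = [(n, st.offsets.get(n, 0)) for n in half]
        u = min(half_info, key=lambda p: (p[1], p[0]))[0]
        forced[u] = {"record": None, "best": None, "half": list(half)}
        st.force_visit(u, on_visit)
        st.run(on_visit)
        info = forced[u]
        if info["best"] is not None:
            v, pos_v = info["best"]
            on_cycle = set(_nodes_on_cycles_through(graph, u))
            rec = CycleRecord(
                cycle_start_node=u,
                cycle_end_node=v,
                cycle_start_pos=st.offsets[u],
                cycle_end_pos=pos_v,
                half_visited=[
                    (n, "on_cycle" if n in on_cycle or _on_some_cycle(graph, n) else "off_cycle")
                    for n in info["half"]
                ],
            )
            info["record"] = rec
            records.append(rec)
        # else: u was off-cycle (or its cycle closed through another forced
        # node); the loop continues with the next stalled state
    return records


def _nodes_on_cycles_through(graph: ColoredDBG, u: str) -> list[str]:
    """Nodes on some cycle through u (u itself if any successor reaches u)."""
    seen = set()
    stack = [v for v in graph.successors(u)]
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        if x == u:
            return [u]
        stack.extend(graph.successors(x))
    return []


def _on_some_cycle(graph: ColoredDBG, n: str) -> bool:
    return bool(_nodes_on_cycles_through(graph, n))


# ---------------------------------------------------------------------------
# cutting-point selection
# ---------------------------------------------------------------------------

def _completed_offsets(graph: ColoredDBG) -> dict[str, int]:
    """Offsets of every node from the forward traversal, forcing through
    cycles (minimal-offset half-visited node first) so the whole cycle
    interval carries position information."""
    st = _State(graph, "forward")
    st.run()
    while st.early_finish:
        half = st.half_visited
        if not half:
            break
        u = min(half, key=lambda n: (st.offsets.get(n, 0), n))
        st.force_visit(u)
        st.run()
    return st.offsets


def _position_tables(graph: ColoredDBG, offsets: dict[str, int], lo: int, hi: int):
    """Per-offset hash tables inside [lo, hi]: offset -> list of nodes.  The
    offset of a node stands for its last base in the k-mer."""
    tables: dict[int, list[str]] = {p: [] for p in range(lo, hi + 1)}
    for node, pos in offsets.items():
        if lo <= pos <= hi:
            tables[pos].append(node)
    return tables


def _point_type(graph: ColoredDBG, nodes_at: list[str]) -> Optional[str]:
    """I: a bridge locus (single full-color degree-1 node — the ideal cut);
    II: not a bridge but involving all samples; III: partial samples."""
    if not nodes_at:
        return None
    union = 0
    for n in nodes_at:
        union |= graph.nodes[n]
    if union != graph.full_color:
        return "III"
    if (
        len(nodes_at) == 1
        and graph.indegree(nodes_at[0]) == 1
        and graph.outdegree(nodes_at[0]) == 1
    ):
        return "I"
    return "II"


def thickness(states: list[tuple[str, int]]) -> int:
    """Number of distinct (base, color) information states at a position.

    The quantity t of the score R = L/t; a single state means every sample
    agrees on the base at this offset.
    """
    return len(set(states))


def score_cut_regions(
    graph: ColoredDBG,
    record: CycleRecord,
    genomes: Sequence[Genome],
) -> list[CutRegion]:
    """Classify every offset in the cycle interval (I bridge / II all-sample /
    III partial), merge adjacent same-information offsets into regions, and
    rank them by R = L/t with bridge preference at ties."""
    lo, hi = record.interval
    if lo > hi:
        raise ValueError("empty cycle interval")
    tables = _position_tables(graph, _completed_offsets(graph), lo, hi)

    # classify each offset
    info: list[tuple[int, Optional[str], int, str]] = []
    for p in range(lo, hi + 1):
        nodes_at = tables[p]
        states = [(n[-1], graph.nodes[n]) for n in nodes_at]
        typ = _point_type(graph, nodes_at)
        t = thickness(states)
        base = states[0][0] if len(set(b for b, _ in states)) == 1 else ""
        info.append((p, typ, t, base))

    # merge runs of identical (type, thickness) information
    regions: list[CutRegion] = []
    i = 0
    while i < len(info):
        p, typ, t, base = info[i]
        if typ is None:
            i += 1
            continue
        j = i
        bases = []
        while j < len(info) and info[j][1] == typ and info[j][2] == t:
            bases.append(info[j][3] or "N")
            j += 1
        L = j - i
        mid = info[i + (L - 1) // 2][0]
        # the searchable segment is the k-mer of the widest-color node at the
        # cut position: it occurs verbatim in every sample carrying it
        cands = tables.get(mid, [])
        seg, seg_color = "", 0
        if cands:
            node = max(cands, key=lambda n: bin(graph.nodes[n]).count("1"))
            seg, seg_color = node, graph.nodes[node]
        regions.append(
            CutRegion(
                interval=(p, info[j - 1][0]),
                point_type=typ,
                L=L,
                t=t,
                bases="".join(bases),
                reference_cut_pos=mid,
                segment=seg,
                segment_color=seg_color,
            )
        )
        i = j

    if not regions or all(r.L == 0 for r in regions):
        # degenerate: fall back to the single position of minimum thickness
        best_p, best_t = min(((p, t) for p, ty, t, _ in info if ty), key=lambda x: x[1])
        cands = tables.get(best_p, [])
        node = max(cands, key=lambda n: bin(graph.nodes[n]).count("1")) if cands else ""
        return [
            CutRegion(
                interval=(best_p, best_p),
                point_type="III",
                L=0,
                t=best_t,
                bases="",
                reference_cut_pos=best_p,
                segment=node,
                segment_color=graph.nodes.get(node, 0),
            )
        ]
    pref = {"I": 0, "II": 1, "III": 2}
    regions.sort(key=lambda r: (-r.R, pref[r.point_type], r.interval[0]))
    return regions


# ---------------------------------------------------------------------------
# sequence cutting and graph reconstruction
# ---------------------------------------------------------------------------

def cut_and_rebuild(
    genomes: Sequence[Genome],
    chosen_region: CutRegion | Sequence[CutRegion],
    k: int,
    anchors: tuple[str, str],
    max_depth: int = 4,
) -> list[ColoredDBG]:
    """Cut every sample at its occurrence of the chosen segment and rebuild
    per-segment acyclic graphs.

    Given a ranked region list, the best region with a searchable consensus
    segment is used.  The region's base segment is searched in each sample; a
    unique hit is cut at its middle, multiple hits at the one nearest the
    reference cutting position.  Each part is re-anchored (the missing
    head/tail supplied) and the per-segment graphs rebuilt; a still-cyclic
    part recurses up to ``max_depth`` times.
    """
    n_bits = len(genomes)
    full = (1 << n_bits) - 1
    if not isinstance(chosen_region, CutRegion):
        ranked = [r for r in chosen_region if r.segment or r.bases]
        # prefer regions whose cut segment is guaranteed in every sample
        all_sample = [r for r in ranked if r.segment_color == full]
        usable = all_sample or ranked
        if not usable:
            raise ValueError("no cut region has a searchable segment")
        chosen_region = usable[0]
    seg = chosen_region.segment or chosen_region.bases
    if not seg or "N" in seg:
        raise ValueError("chosen region has no searchable segment")
    ref_mid = chosen_region.reference_cut_pos

    firsts: list[Genome] = []
    seconds: list[Genome] = []
    for g in genomes:
        hits = _find_all(g.sequence, seg)
        if not hits:
            raise ValueError(
                f"cut segment {seg!r} not found in sample {g.sample_id!r}"
            )
        if len(hits) == 1:
            start = hits[0]
        else:
            start = min(hits, key=lambda h: abs(h + len(seg) // 2 - ref_mid))
        cut = start + len(seg) // 2
        cut = max(1, min(cut, len(g.sequence) - 1))
        firsts.append(Genome(g.sample_id, g.sequence[:cut]))
        seconds.append(Genome(g.sample_id, g.sequence[cut:]))

    graphs: list[ColoredDBG] = []
    for part in (firsts, seconds):
        graphs.extend(_rebuild(part, k, anchors, max_depth))
    return graphs


def _rebuild(genomes: list[Genome], k: int, anchors, depth: int) -> list[ColoredDBG]:
    g = build_graph(genomes, k, anchors)
    if not detect_cycles(g):
        return [g]
    if depth <= 0:
        raise RuntimeError("cycle cutting did not converge to acyclic graphs")
    recs = locate_cycle_intervals(g)
    if not recs:
        raise RuntimeError("stalled traversal but no locatable cycle")
    regions = score_cut_regions(g, recs[0], genomes)
    return cut_and_rebuild(genomes, regions, k, anchors, max_depth=depth - 1)


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out
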