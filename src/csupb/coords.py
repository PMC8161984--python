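"""Tri-tuple base coordinates and six-tuple path coordinates.

Each graph node gets a base location (position, bubid, basecolor): its final
offset, the smallest (deepest) cSupB containing it (-1 on bridges outside
all cSupBs), and its color.  A walk gets a path location (startpos, startbub,
endpos, endbub, pathbub, pathcolor) where pathbub is the smallest cSupB
containing the whole walk, or -n when the walk spans n root cSupBs; the path
color is the intersection of its node colors.  Linear annotations (VCF
records, GTF features) on the designated reference are lifted onto these
coordinates through the reference-position map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .decompose import CSupBTree
from .graph import ColoredDBG, ColorSet
from .traversal import OffsetMap

__all__ = [
    "BaseLocation",
    "PathLocation",
    "CoordinateSystem",
    "relate_paths",
]


@dataclass(frozen=True)
class BaseLocation:
    position: int
    bubid: int            # cSupB order, or -1 on a bridge
    basecolor: str

    def astuple(self) -> tuple[int, int, str]:
        return (self.position, self.bubid, self.basecolor)


@dataclass(frozen=True)
class PathLocation:
    startpos: int
    startbub: int
    endpos: int
    endbub: int
    pathbub: int          # cSupB order, or -n when spanning n root cSupBs
    pathcolor: str

    def astuple(self) -> tuple:
        return (
            self.startpos,
            self.startbub,
            self.endpos,
            self.endbub,
            self.pathbub,
            self.pathcolor,
        )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.startpos, self.endpos)


class CoordinateSystem:
    """Node <-> coordinate queries over a decomposed graph."""

    def __init__(self, graph: ColoredDBG, tree: CSupBTree, offsets: OffsetMap):
        self.graph = graph
        self.tree = tree
        self.offsets = offsets
        # node -> deepest containing bubble (max level, ties to smallest order)
        self._deepest: dict[str, int] = {}
        for order in sorted(tree.bubbles):
            b = tree[order]
            for n in b.nodes:
                cur = self._deepest.get(n)
                if cur is None or (b.level, -order) > (tree[cur].level, -cur):
                    self._deepest[n] = order
        self._by_tuple = {}
        for n in graph.nodes:
            bl = self.base_location(n)
            self._by_tuple[bl.astuple()] = n

    # -- base locations ----------------------------------------------------

    def base_location(self, node: str, representative: bool = False) -> BaseLocation:
        """The (position, bubid, basecolor) triple of a node.

        With ``representative=True`` the base color is a sample id containing
        the node instead of the 0/1 string (the simpler rendering).
        """
        if node not in self.graph.nodes:
            raise KeyError(f"unknown node {node!r}")
        color = self.graph.color(node)
        basecolor = (
            self.graph.sample_ids[color.samples()[0]] if representative else str(color)
        )
        return BaseLocation(
            position=self.offsets.final[node],
            bubid=self._deepest.get(node, -1),
            basecolor=basecolor,
        )

    def node_at(self, location: BaseLocation | tuple) -> str:
        """Reverse lookup: the unique node at a base location."""
        key = location.astuple() if isinstance(location, BaseLocation) else tuple(location)
        return self._by_tuple[key]

    # -- path locations ----------------------------------------------------

    def path_location(self, path: Sequence[str]) -> PathLocation:
        g = self.graph
        if not path:
            raise ValueError("empty path")
        for u, v in zip(path, path[1:]):
            if v not in g.successors(u):
                raise ValueError(f"{u}->{v} is not an edge; path is disconnected")
        color = g.full_color
        for n in path:
            color &= g.nodes[n]
        start, end = path[0], path[-1]
        startbub = self._deepest.get(start, -1)
        endbub = self._deepest.get(end, -1)
        pathbub = self._smallest_containing(path)
        if startbub == -1 and pathbub > 0:
            startbub = pathbub
        if endbub == -1 and pathbub > 0:
            endbub = pathbub
        return PathLocation(
            startpos=self.offsets.final[start],
            startbub=startbub,
            endpos=self.offsets.final[end],
            endbub=endbub,
            pathbub=pathbub,
            pathcolor=str(ColorSet(color, g.n_samples)),
        )

    def _smallest_containing(self, path: Sequence[str]) -> int:
        """Deepest cSupB containing every non-bridge node of the walk, else
        -n for a walk spanning n root cSupBs."""
        tree = self.tree
        in_bubble = [n for n in path if n in self._deepest]
        if in_bubble:
            best = None
            for order, b in tree.bubbles.items():
                if all(n in b.nodes for n in in_bubble):
                    if best is None or (b.level, -order) > (
                        tree[best].level,
                        -best,
                    ):
                        best = order
            if best is not None:
                return best
        roots = set()
        for n in in_bubble:
            o = self._deepest[n]
            while tree[o].parent is not None:
                o = tree[o].parent
            roots.add(o)
        return -max(len(roots), 1)

    # -- annotation lifting ------------------------------------------------

    def node_at_refpos(self, refmap_inv: dict[int, str], pos: int) -> Optional[str]:
        return refmap_inv.get(pos)

    def map_position(
        self, ref_path: Sequence[str], pos: int
    ) -> Optional[BaseLocation]:
        """Base location of a 1-based reference position (the node whose
        k-mer ends at that base)."""
        if not 1 <= pos < len(ref_path):
            return None
        return self.base_location(ref_path[pos])

    def map_interval(
        self, ref_path: Sequence[str], start: int, end: int
    ) -> Optional[PathLocation]:
        """Path location of a 1-based inclusive reference interval."""
        if start > end or start < 1 or end >= len(ref_path):
            return None
        return self.path_location(list(ref_path[start : end + 1]))

    def spanned_csupbs(self, ref_path: Sequence[str], start: int, end: int) -> int:
        """Number of distinct deepest cSupBs a reference interval touches."""
        orders = set()
        for p in range(start, min(end + 1, len(ref_path))):
            o = self._deepest.get(ref_path[p])
            if o is not None:
                orders.add(o)
        return len(orders)


def map_annotation(
    coords: CoordinateSystem,
    ref_id: str,
    records: Sequence[dict],
    kind: str = "vcf",
) -> list[dict]:
    """Lift linear annotation records onto graph coordinates.

    VCF records map their position to a base location; GTF features map
    their 1-based inclusive interval to a path location.  Each output row
    reports whether the locus sits in a cSupB or on a bridge and, for
    intervals, how many cSupBs they span.  Out-of-range positions are
    flagged, not fatal.
    """
    ref_path = coords.graph.sample_paths[ref_id]
    out: list[dict] = []
    for rec in records:
        if kind == "vcf":
            pos = rec["pos"]
            bl = coords.map_position(ref_path, pos)
            row = {"pos": pos, "ref": rec.get("ref"), "alts": rec.get("alts")}
            if bl is None:
                row.update(status="out_of_range")
            else:
                row.update(
                    status="ok",
                    position=bl.position,
                    bubid=bl.bubid,
                    basecolor=bl.basecolor,
                    in_csupb=bl.bubid != -1,
                )
        elif kind == "gtf":
            start, end = rec["start"], rec["end"]
            pl = coords.map_interval(ref_path, start, end)
            row = {"start": start, "end": end, "feature": rec.get("feature")}
            if pl is None:
                row.update(status="out_of_range")
            else:
                row.update(
                    status="ok",
                    path_location=pl.astuple(),
                    spanned_csupbs=coords.spanned_csupbs(ref_path, start, end),
                    on_bridge_only=coords.spanned_csupbs(ref_path, start, end) == 0,
                )
        else:
            raise ValueError("kind must be 'vcf' or 'gtf'")
        out.append(row)
    return out


def relate_paths(
    p1: PathLocation, p2: PathLocation, tree: CSupBTree
) -> tuple[str, Optional[dict]]:
    """Classify two path locations as separation / inclusion / intersection.

    Disjoint offset intervals separate; interval inclusion together with
    color inclusion is inclusion; everything else intersects.  When the
    intervals intersect but the colors are disjoint, the nearest common
    parent bubble of the two pathbubs (with its color) is returned as context
    for similarity analysis, or the all-samples color when the paths span
    root cSupBs.
    """
    a1, b1 = sorted(p1.interval)
    a2, b2 = sorted(p2.interval)
    if b1 < a2 or b2 < a1:
        return "separation", None
    c1 = ColorSet.from_string(p1.pathcolor)
    c2 = ColorSet.from_string(p2.pathcolor)
    inc_interval = (a1 <= a2 and b2 <= b1) or (a2 <= a1 and b1 <= b2)
    inc_color = c1.issubset(c2) or c2.issubset(c1)
    if inc_interval and inc_color:
        return "inclusion", None
    context = None
    if c1.intersection(c2).isempty():
        anc = _nearest_common_parent(tree, p1.pathbub, p2.pathbub)
        if anc is None:
            context = {"bubble": None, "color": "1" * c1.n}
        else:
            context = {"bubble": anc, "color": str(tree[anc].colorset)}
    return "intersection", context


def _nearest_common_parent(tree: CSupBTree, o1: int, o2: int) -> Optional[int]:
    if o1 <= 0 or o2 <= 0:
        return None
    anc1 = []
    o = o1
    while o is not None:
        anc1.append(o)
        o = tree[o].parent
    o = o2
    while o is not None:
        if o in anc1:
            return o
        o = tree[o].parent
    return None
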