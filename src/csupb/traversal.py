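"""Postorder-like graph traversal and longest-path offset values.

A node may be visited only when all of its incoming nodes (in the traversal
direction) have been visited.  Offsets follow pos(v) = max over incoming u of
pos(u) + 1 with pos(start) = 1, i.e. the longest-path distance from the start
node.  Final offsets are derived from the reverse (against-edge) traversal by
subtraction, which places indel offset jumps next to the forward-direction
source node of a bubble rather than its sink.

On a cyclic graph the traversal stalls before visiting every node ("finished
in advance"); the nodes stuck in the half-visited state seed cycle location.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

from .graph import ColoredDBG

__all__ = [
    "VisitState",
    "TraversalResult",
    "OffsetMap",
    "postorder_traverse",
    "final_offsets",
    "CyclicGraphError",
]


class CyclicGraphError(RuntimeError):
    """Raised when an operation requiring a DAG meets a cycle."""


class VisitState(str, Enum):
    UNVISITED = "unvisited"
    HALF_VISITED = "half_visited"
    TO_BE_VISITED = "to_be_visited"
    FULLY_VISITED = "fully_visited"


@dataclass
class TraversalResult:
    visit_order: list[str]
    states: dict[str, VisitState]
    offsets: dict[str, int]          # tentative for non-fully-visited nodes
    early_finish: bool
    half_visited: list[str]


@dataclass
class OffsetMap:
    """Forward, reverse (pre-) and final longest-path offsets per node."""

    forward: dict[str, int]
    pre: dict[str, int]
    final: dict[str, int]


@dataclass
class _State:
    """Resumable traversal state (used by the cycle handler to force nodes
    fully visited and continue)."""

    graph: ColoredDBG
    direction: str
    states: dict[str, VisitState] = field(default_factory=dict)
    offsets: dict[str, int] = field(default_factory=dict)
    seen_parents: dict[str, int] = field(default_factory=dict)
    queue: deque = field(default_factory=deque)
    visit_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = self.graph
        if self.direction == "forward":
            self.succ, self.pred = g.successors, g.predecessors
            source = g.start_node
        else:
            self.succ, self.pred = g.predecessors, g.successors
            source = g.end_node
        for n in g.nodes:
            self.states[n] = VisitState.UNVISITED
        self.states[source] = VisitState.TO_BE_VISITED
        self.offsets[source] = 1
        self.queue.append(source)
        self.source = source

    def run(self, on_visit: Optional[Callable[[str], None]] = None) -> None:
        """Drain the ready queue (FIFO on discovery order)."""
        while self.queue:
            u = self.queue.popleft()
            self.states[u] = VisitState.FULLY_VISITED
            self.visit_order.append(u)
            if on_visit is not None:
                on_visit(u)
            self._notify_children(u)

    def _notify_children(self, u: str) -> None:
        pos_u = self.offsets[u]
        for v in self.succ(u):
            if self.states[v] is VisitState.FULLY_VISITED:
                continue
            self.offsets[v] = max(self.offsets.get(v, 0), pos_u + 1)
            self.seen_parents[v] = self.seen_parents.get(v, 0) + 1
            if self.seen_parents[v] == len(self.pred(v)):
                self.states[v] = VisitState.TO_BE_VISITED
                self.queue.append(v)
            elif self.states[v] is VisitState.UNVISITED:
                self.states[v] = VisitState.HALF_VISITED

    def force_visit(self, u: str, on_visit: Optional[Callable[[str], None]] = None) -> None:
        """Mark a half-visited node fully visited at its tentative offset and
        resume (cycle interval location, step 3)."""
        self.states[u] = VisitState.FULLY_VISITED
        self.visit_order.append(u)
        if on_visit is not None:
            on_visit(u)
        self._notify_children(u)

    @property
    def early_finish(self) -> bool:
        return any(s is not VisitState.FULLY_VISITED for s in self.states.values())

    @property
    def half_visited(self) -> list[str]:
        return [n for n, s in self.states.items() if s is VisitState.HALF_VISITED]


def postorder_traverse(
    graph: ColoredDBG,
    direction: str = "forward",
    on_visit: Optional[Callable[[str], None]] = None,
) -> TraversalResult:
    """Run the postorder-like traversal from the unique source of the chosen
    direction.  Ready nodes are served FIFO on discovery order, which fixes a
    reproducible visit order (and hence cSupB discovery order)."""
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    st = _State(graph, direction)
    st.run(on_visit)
    early = st.early_finish
    if early and not st.half_visited:
        # a cycle stall always leaves half-visited nodes; none means the
        # unvisited remainder is disconnected from the source entirely
        raise RuntimeError("nodes unreachable from the source in an acyclic graph")
    return TraversalResult(
        visit_order=st.visit_order,
        states=st.states,
        offsets=st.offsets,
        early_finish=early,
        half_visited=st.half_visited,
    )


def final_offsets(graph: ColoredDBG) -> OffsetMap:
    """Forward, pre- and final offsets of an acyclic graph.

    final(v) = pre(start) + 1 - pre(v), so final(start) = 1 and final is the
    longest-path distance from the start measured through the reverse
    traversal; in a bubble with unequal branch lengths the offset jump sits on
    the short branch's edge out of the (forward) source node.
    """
    fwd = postorder_traverse(graph, "forward")
    if fwd.early_finish:
        raise CyclicGraphError(
            "graph has cycles; locate and cut them with the cycle handler first"
        )
    rev = postorder_traverse(graph, "reverse")
    pre = rev.offsets
    base = pre[graph.start_node] + 1
    final = {n: base - p for n, p in pre.items()}
    return OffsetMap(forward=fwd.offsets, pre=pre, final=final)
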