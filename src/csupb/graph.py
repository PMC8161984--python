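"""Colored de Bruijn graph construction from haplotype genome sets.

A set of haplotype sequences (one per sample, one designated reference) is
turned into a node-centric colored de Bruijn graph: nodes are k-mers, edges
are (k-1)-overlaps, and both carry a per-sample color bit-vector.  Random
anchor segments prepended/appended to every sample guarantee a unique start
and end node, and choosing k larger than the longest repeat segment of any
sample makes the graph acyclic, so that each sample spells exactly one
start-to-end path.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Genome",
    "ColorSet",
    "ColoredDBG",
    "GraphConstructionError",
    "sanitize_genomes",
    "longest_repeat_length",
    "choose_k",
    "generate_anchors",
    "build_graph",
]

_DNA = frozenset("ACGT")

# IUPAC degenerate codes and the bases they stand for (used for sanity
# messages only; replacement is by majority vote over the other samples).
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class GraphConstructionError(ValueError):
    """Raised when the inputs cannot produce a valid anchored colored dBG."""


@dataclass(frozen=True)
class ColorSet:
    """Fixed-length sample-membership bit-vector.

    Bit ``i`` corresponds to the i-th sample in input order; the string
    rendering puts sample 0 leftmost, matching renderings like ``"110"``.
    """

    bits: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("ColorSet needs at least one sample")
        if self.bits < 0 or self.bits >> self.n:
            raise ValueError("color bits out of range for sample count")

    @classmethod
    def from_string(cls, s: str) -> "ColorSet":
        bits = 0
        for i, ch in enumerate(s):
            if ch == "1":
                bits |= 1 << i
            elif ch != "0":
                raise ValueError(f"invalid color string {s!r}")
        return cls(bits, len(s))

    @classmethod
    def from_samples(cls, samples: Iterable[int], n: int) -> "ColorSet":
        bits = 0
        for i in samples:
            bits |= 1 << i
        return cls(bits, n)

    def __str__(self) -> str:
        return "".join("1" if self.bits >> i & 1 else "0" for i in range(self.n))

    def __contains__(self, sample: int) -> bool:
        return bool(self.bits >> sample & 1)

    def samples(self) -> list[int]:
        return [i for i in range(self.n) if self.bits >> i & 1]

    def count(self) -> int:
        return bin(self.bits).count("1")

    def union(self, other: "ColorSet") -> "ColorSet":
        return ColorSet(self.bits | other.bits, self.n)

    def intersection(self, other: "ColorSet") -> "ColorSet":
        return ColorSet(self.bits & other.bits, self.n)

    def issubset(self, other: "ColorSet") -> bool:
        return self.bits & ~other.bits == 0

    def isempty(self) -> bool:
        return self.bits == 0


@dataclass
class Genome:
    """A sanitized haplotype sequence plus its degenerate-base repair log.

    ``modifications`` records every replaced position as
    (1-based position, original base, replacement base).
    """

    sample_id: str
    sequence: str
    modifications: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.sample_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_genomes(raw_genomes: Sequence[tuple[str, str]]) -> list[Genome]:
    """Replace degenerate bases by the most frequent base of the other samples.

    Ties are broken by the lexicographically smallest base so the output is
    deterministic.  Every replacement is logged on the affected genome.
    Sequences may have different lengths; the column vote uses whichever other
    samples cover the position.
    """
    if len(raw_genomes) < 2:
        raise ValueError("need at least two genomes")
    seqs = []
    for sid, seq in raw_genomes:
        if not seq:
            raise ValueError(f"genome {sid!r} has an empty sequence")
        s = seq.upper().replace("U", "T")
        bad = set(s) - _DNA - set(_IUPAC)
        if bad:
            raise ValueError(f"genome {sid!r} has non-IUPAC characters {sorted(bad)}")
        seqs.append((sid, s))

    out: list[Genome] = []
    for idx, (sid, s) in enumerate(seqs):
        chars = list(s)
        mods: list[tuple[int, str, str]] = []
        for pos, ch in enumerate(chars):
            if ch in _DNA:
                continue
            votes = Counter()
            for jdx, (_, other) in enumerate(seqs):
                if jdx == idx or pos >= len(other):
                    continue
                if other[pos] in _DNA:
                    votes[other[pos]] += 1
            if not votes:
                raise ValueError(
                    f"cannot repair degenerate base {ch!r} at position {pos + 1}: "
                    "no other sample offers a concrete base there"
                )
            best = max(votes.values())
            repl = min(b for b, c in votes.items() if c == best)
            chars[pos] = repl
            mods.append((pos + 1, ch, repl))
        out.append(Genome(sid, "".join(chars), mods))
    return out


def longest_repeat_length(sequence: str) -> int:
    """Length of the longest substring occurring at least twice.

    Occurrences may overlap.  Computed exactly via a rank-doubling suffix
    array and Kasai's LCP construction (longest repeat = max LCP value).
    Returns 0 for sequences with no repeated character.
    """
    n = len(sequence)
    if n < 2:
        return 0
    # suffix array by rank doubling
    rank = [ord(c) for c in sequence]
    sa = sorted(range(n), key=lambda i: rank[i])
    tmp = [0] * n
    k = 1
    while True:
        def key(i: int) -> tuple[int, int]:
            return (rank[i], rank[i + k] if i + k < n else -1)

        sa.sort(key=key)
        tmp[sa[0]] = 0
        for i in range(1, n):
            tmp[sa[i]] = tmp[sa[i - 1]] + (key(sa[i - 1]) < key(sa[i]))
        rank = tmp[:]
        if rank[sa[-1]] == n - 1:
            break
        k <<= 1
    # Kasai LCP
    inv = [0] * n
    for i, s in enumerate(sa):
        inv[s] = i
    h = 0
    best = 0
    for i in range(n):
        if inv[i] > 0:
            j = sa[inv[i] - 1]
            while i + h < n and j + h < n and sequence[i + h] == sequence[j + h]:
                h += 1
            best = max(best, h)
            if h:
                h -= 1
        else:
            h = 0
    return best


def max_repeat_length(genomes: Sequence[Genome]) -> int:
    """K = max over samples of the longest repeat segment length."""
    return max(longest_repeat_length(g.sequence) for g in genomes)


def choose_k(
    genomes: Sequence[Genome],
    requested_k: Optional[int] = None,
    warn: Optional[list[str]] = None,
) -> int:
    """Pick the k-mer length.

    Defaults to K+1 where K is the longest repeat segment length over all
    samples; any k > K makes the graph acyclic.  A requested k ≤ K is allowed
    (the cycle handler exists for that case) but a warning is recorded.
    """
    if requested_k is not None and requested_k < 2:
        raise ValueError("k must be at least 2")
    K = max_repeat_length(genomes)
    k = requested_k if requested_k is not None else max(K + 1, 3)
    if k <= K:
        msg = (
            f"k={k} does not exceed the longest repeat segment length K={K}; "
            "the graph may contain cycles and require cycle handling"
        )
        import warnings

        warnings.warn(msg, stacklevel=2)
        if warn is not None:
            warn.append(msg)
    return k


def generate_anchors(
    k: int,
    genomes: Sequence[Genome],
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[str, str]:
    """Draw the head/tail anchor segments: length-k ACGT strings absent from
    every input sequence, distinct from each other, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = random.Random(seed)
    seqs = [g.sequence for g in genomes]

    def draw() -> str:
        for _ in range(max_tries):
            cand = "".join(rng.choice("ACGT") for _ in range(k))
            if not any(cand in s for s in seqs):
                return cand
        raise GraphConstructionError(
            f"could not find a length-{k} anchor absent from all inputs "
            f"after {max_tries} tries"
        )

    head = draw()
    for _ in range(max_tries):
        tail = draw()
        if tail != head:
            return head, tail
    raise GraphConstructionError("could not find two distinct anchors")


@dataclass
class ColoredDBG:
    """Node-centric colored de Bruijn graph with anchored sample paths."""

    k: int
    sample_ids: list[str]
    nodes: dict[str, int]                    # k-mer -> color bitmask
    out_edges: dict[str, dict[str, int]]     # u -> {v: color bitmask}
    in_edges: dict[str, dict[str, int]]      # v -> {u: color bitmask}
    start_node: str
    end_node: str
    anchors: tuple[str, str]
    sample_paths: dict[str, list[str]]       # sample id -> node sequence

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def full_color(self) -> int:
        return (1 << self.n_samples) - 1

    def color(self, node: str) -> ColorSet:
        return ColorSet(self.nodes[node], self.n_samples)

    def colorset(self, bits: int) -> ColorSet:
        return ColorSet(bits, self.n_samples)

    def successors(self, node: str) -> dict[str, int]:
        return self.out_edges.get(node, {})

    def predecessors(self, node: str) -> dict[str, int]:
        return self.in_edges.get(node, {})

    def outdegree(self, node: str) -> int:
        return len(self.out_edges.get(node, ()))

    def indegree(self, node: str) -> int:
        return len(self.in_edges.get(node, ()))

    def is_supernode(self, node: str) -> bool:
        return self.outdegree(node) > 1 or self.indegree(node) > 1

    def spell_path(self, path: Sequence[str]) -> str:
        """Concatenate node labels along a walk, collapsing (k-1)-overlaps."""
        if not path:
            return ""
        return path[0] + "".join(p[-1] for p in path[1:])

    def anchored_sequence(self, sample_id: str, genomes: Sequence[Genome]) -> str:
        g = next(g for g in genomes if g.sample_id == sample_id)
        return self.anchors[0] + g.sequence + self.anchors[1]

    def validate(self) -> None:
        """Check the structural invariants (overlaps, colors, unique ends)."""
        for u, targets in self.out_edges.items():
            for v in targets:
                if u[1:] != v[:-1]:
                    raise AssertionError(f"edge {u}->{v} lacks a (k-1)-overlap")
        starts = [n for n in self.nodes if self.indegree(n) == 0]
        ends = [n for n in self.nodes if self.outdegree(n) == 0]
        if starts != [self.start_node] or ends != [self.end_node]:
            raise AssertionError(
                f"expected unique start/end; got starts={starts} ends={ends}"
            )
        # node/edge colors are exact unions over sample paths
        node_cols: dict[str, int] = {n: 0 for n in self.nodes}
        for i, sid in enumerate(self.sample_ids):
            for node in self.sample_paths[sid]:
                node_cols[node] |= 1 << i
        if node_cols != self.nodes:
            raise AssertionError("node colors are not the union over sample paths")


def build_graph(
    genomes: Sequence[Genome],
    k: int,
    anchors: tuple[str, str],
) -> ColoredDBG:
    """Build the anchored colored de Bruijn graph.

    Each sample contributes the k-mers of head + sequence + tail; node and
    edge colors are the exact union over the samples visiting them.
    """
    head, tail = anchors
    if len(head) != k or len(tail) != k:
        raise GraphConstructionError("anchors must have length k")
    nodes: dict[str, int] = {}
    out_edges: dict[str, dict[str, int]] = {}
    in_edges: dict[str, dict[str, int]] = {}
    sample_paths: dict[str, list[str]] = {}
    sample_ids = [g.sample_id for g in genomes]
    if len(set(sample_ids)) != len(sample_ids):
        raise GraphConstructionError("duplicate sample ids")

    for i, g in enumerate(genomes):
        seq = head + g.sequence + tail
        if len(seq) < k + 1:
            raise GraphConstructionError(
                f"sample {g.sample_id!r} is shorter than k after anchoring"
            )
        bit = 1 << i
        path = [seq[j : j + k] for j in range(len(seq) - k + 1)]
        sample_paths[g.sample_id] = path
        prev = None
        for kmer in path:
            nodes[kmer] = nodes.get(kmer, 0) | bit
            if prev is not None:
                out_edges.setdefault(prev, {})
                out_edges[prev][kmer] = out_edges[prev].get(kmer, 0) | bit
                in_edges.setdefault(kmer, {})
                in_edges[kmer][prev] = in_edges[kmer].get(prev, 0) | bit
            prev = kmer

    graph = ColoredDBG(
        k=k,
        sample_ids=sample_ids,
        nodes=nodes,
        out_edges=out_edges,
        in_edges=in_edges,
        start_node=head,
        end_node=tail,
        anchors=(head, tail),
        sample_paths=sample_paths,
    )
    if graph.indegree(head) != 0 or graph.outdegree(tail) != 0:
        raise GraphConstructionError(
            "anchor k-mers recur inside the anchored sequences; "
            "re-draw anchors with a different seed"
        )
    return graph
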