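"""End-to-end orchestration: build -> decompose -> variants -> coordinates.

The pipeline is the library counterpart of the CLI: it sanitizes the inputs,
chooses k, draws anchors, builds the graph, computes offsets, finds the
cSupB forest, calls variants against the designated reference and returns
everything needed for coordinate queries and file export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .coords import CoordinateSystem
from .cycles import detect_cycles
from .decompose import CSupBTree, build_csupb_tree, find_csupbs
from .graph import (
    ColoredDBG,
    Genome,
    build_graph,
    choose_k,
    generate_anchors,
    sanitize_genomes,
)
from .traversal import OffsetMap, final_offsets
from .variants import LocusVariant, NodeVariant, call_variants

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    genomes: list[Genome]
    graph: ColoredDBG
    k: int
    offsets: OffsetMap
    tree: CSupBTree
    coords: CoordinateSystem
    node_variants: list[NodeVariant]
    locus_variants: list[LocusVariant]
    ref_id: str
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    raw_genomes: Sequence[tuple[str, str]],
    ref_id: str,
    k: Optional[int] = None,
    seed: int = 0,
    anchors: Optional[tuple[str, str]] = None,
) -> PipelineResult:
    """Run the full analysis on raw (id, sequence) pairs.

    Raises if the graph is cyclic at the chosen k — locate and cut the
    cycles first (``csupb.cycles``) or pick a larger k.
    """
    ids = [sid for sid, _ in raw_genomes]
    if ref_id not in ids:
        raise ValueError(f"reference id {ref_id!r} not among inputs {ids}")
    warns: list[str] = []
    genomes = sanitize_genomes(raw_genomes)
    k = choose_k(genomes, k, warn=warns)
    if anchors is None:
        anchors = generate_anchors(k, genomes, seed=seed)
    graph = build_graph(genomes, k, anchors)
    half = detect_cycles(graph)
    if half:
        raise RuntimeError(
            f"graph is cyclic at k={k} ({len(half)} half-visited nodes); "
            "use the cycle handler to locate and cut the cycles"
        )
    offsets = final_offsets(graph)
    tree = build_csupb_tree(find_csupbs(graph))
    coords = CoordinateSystem(graph, tree, offsets)
    node_variants, locus_variants = call_variants(
        graph, tree, offsets, genomes, ref_id
    )
    return PipelineResult(
        genomes=genomes,
        graph=graph,
        k=k,
        offsets=offsets,
        tree=tree,
        coords=coords,
        node_variants=node_variants,
        locus_variants=locus_variants,
        ref_id=ref_id,
        warnings=warns,
    )
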