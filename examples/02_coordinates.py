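"""Tri-tuple base coordinates and six-tuple path coordinates on the toy
graph, plus the relation between two sequence paths.

A base location (position, bubid, basecolor) pins a k-mer node by its
longest-path offset, its deepest enclosing cSupB (-1 on a bridge) and the
samples carrying it; a path location extends this to a walk.
"""

from csupb import (
    CoordinateSystem,
    build_csupb_tree,
    build_graph,
    final_offsets,
    find_csupbs,
    relate_paths,
)
from csupb.graph import Genome

genomes = [
    Genome("s1", "CAGGGTGTATGACCC"),
    Genome("s2", "CACGGGAGTATAACCC"),
    Genome("s3", "CACTTCCGTATAACCC"),
]
graph = build_graph(genomes, k=3, anchors=("GAT", "ATT"))
offsets = final_offsets(graph)
tree = build_csupb_tree(find_csupbs(graph))
coords = CoordinateSystem(graph, tree, offsets)

for node in ("TCA", "GGG", "CCC"):
    print(f"base location of {node}: {coords.base_location(node).astuple()}")

kmers = lambda s: [s[i : i + 3] for i in range(len(s) - 2)]
pa = coords.path_location(kmers("CAGGGTGTA"))   # sample 1 through the bubble
pb = coords.path_location(kmers("GGGAGTA"))     # sample 2 joining at GGG
pc = coords.path_location(kmers("ATAACCC"))     # samples 2+3 downstream
print(f"path a = {pa.astuple()}")
print(f"path b = {pb.astuple()}")
print(f"path c = {pc.astuple()}")
rel, ctx = relate_paths(pa, pb, tree)
print(f"a vs b: {rel} (context {ctx}) -- they share nodes such as GGG")
print(f"a vs c: {relate_paths(pa, pc, tree)[0]} -- disjoint offset intervals")
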