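"""Build a colored de Bruijn graph from three toy haplotypes and decompose
it into the colored-superbubble (cSupB) forest.

The three sequences differ by one insertion and three substitutions; at
k = 3 their anchored graph contains five cSupBs whose discovery order,
colors and parentage are printed below.
"""

from csupb import build_csupb_tree, build_graph, final_offsets, find_csupbs
from csupb.graph import Genome

genomes = [
    Genome("s1", "CAGGGTGTATGACCC"),
    Genome("s2", "CACGGGAGTATAACCC"),
    Genome("s3", "CACTTCCGTATAACCC"),
]
graph = build_graph(genomes, k=3, anchors=("GAT", "ATT"))
offsets = final_offsets(graph)
bubbles = find_csupbs(graph)
tree = build_csupb_tree(bubbles)

print(f"graph: {len(graph.nodes)} nodes, k={graph.k}, samples={graph.sample_ids}")
print("cSupBs in discovery order (source, sink, color):")
for b in bubbles:
    parent = tree[b.order].parent
    print(
        f"  bub{b.order}: <{b.source},{b.sink},{b.colorset}>  "
        f"level={tree[b.order].level} parent={parent if parent else '-'}"
    )
print(f"roots: {tree.roots}  (a root cSupB carries every sample)")
print(f"final offset of TCA = {offsets.final['TCA']}  (longest-path distance "
      "from the start anchor; indel gaps sit on edges leaving a source node)")
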