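# csupb — colored-superbubble analysis of de Bruijn graph pangenomes

`csupb` organizes a set of highly similar haplotype genomes (one designated
reference) into an anchored, acyclic **colored de Bruijn graph** and analyzes
its spatial structure instead of aligning sequences. It is aimed at
population-genomics work on small, high-quality haplotype sets —
mitochondrial genomes are the motivating scale — where one wants graph-native
coordinates, per-sample variant calls and annotation lift-over without a
multiple sequence alignment.

## The model

Nodes are k-mers, edges are (k−1)-overlaps, and both carry a **color**
bit-vector recording which samples traverse them. Random length-k anchor
segments added to the front and end of every sequence give the graph a unique
start and end node, and choosing k greater than the longest repeat segment
length K of any sample makes it a DAG in which each sample spells exactly one
start-to-end path.

The analysis rests on three ideas:

* **Colored superbubbles (cSupBs).** A cSupB ⟨s, t, C⟩ is a superbubble
  (reachability, matching, acyclicity, minimality) in the subgraph induced by
  the nodes whose color intersects the color set C. All cSupBs are found in
  one reverse traversal using a matching principle on edge colors, and they
  organize into a forest: bubbles carrying every sample are roots (level 1),
  and each other bubble's parent is the nearest later-discovered bubble that
  contains it.
* **Offset values.** pos(v) = max over incoming u of pos(u) + 1, i.e. the
  longest-path distance from the start node. Final offsets come from the
  reverse traversal by subtraction, which places an indel's length jump on
  the edges leaving a bubble's source node — exactly where variants are
  called.
* **Tri-tuple coordinates.** Every node gets `(position, bubid, basecolor)`:
  its final offset, its deepest enclosing cSupB (−1 on bridges) and its
  color. A walk gets the six-tuple `(startpos, startbub, endpos, endbub,
  pathbub, pathcolor)`, and two walks relate as separation, intersection or
  inclusion from their offset intervals and colors.

Variant calling assumes each cSupB source node marks one variant: branch
gaps type it (both zero → substitution; gap on the reference branch →
insertion; gap on an alternate branch → deletion; irreducible ambiguity →
"unsure" type 4), nested gaps are discounted through the bubble tree, and a
reference-position map turns node variants into VCF records. Indels of
50 bp or more are out of scope. When k is chosen at or below K the graph is
cyclic; the package locates each cycle's offset interval from the stalled
traversal, scores cutting points by R = L/t (run length of same-information
loci over thickness, bridges preferred) and cuts the sequences into acyclic
per-segment graphs.

## Worked example

`examples/01_build_and_decompose.py` builds the three-haplotype toy graph
(k = 3) and prints:

```
graph: 34 nodes, k=3, samples=['s1', 's2', 's3']
cSupBs in discovery order (source, sink, color):
  bub1: <TAT,ACC,111>  level=1 parent=-
  bub2: <GGG,GTA,110>  level=2 parent=5
  bub3: <CAC,GTA,011>  level=2 parent=5
  bub4: <TCA,GGG,110>  level=2 parent=5
  bub5: <TCA,GTA,111>  level=1 parent=-
roots: [1, 5]  (a root cSupB carries every sample)
final offset of TCA = 3  ...
```

Five bubbles are discovered during the reverse traversal; bub5 (all three
samples, ⟨TCA,GTA⟩) is the parent of the three bubbles nested inside it, and
bub1 is a second root. The node TCA sits at longest-path offset 3 inside
bubble 4, so its base location is `(3, 4, '111')`; the bridge node CCC gets
`(17, -1, '111')`. Running `examples/03_call_variants.py` on a simulated
5-sample population prints the VCF-style calls (position, alleles, type
code 1/2/3/4, affected-sample color) and their location-mapped precision and
recall against the simulation truth; `examples/05_snp_benchmark.py` shows
the substitution-only setting where precision is exactly 1.0.

The same functionality is exposed as a CLI:

```bash
csupb simulate --length 16569 --samples 10 --snp 100 --seed 1 --out-dir sim/
csupb build     --fasta sim/population.fa --ref-id REF --k 28 --out graph.json
csupb decompose --graph graph.json --out-prefix run1        # CST/CSDI/OVI/NNI
csupb variants  --fasta sim/population.fa --ref-id REF --k 28 --out calls.vcf
csupb evaluate  --calls calls.vcf --truth sim/truth.vcf --mode location
csupb cycles    --fasta sim/population.fa --k 18 --out ccp.tsv
```

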