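# Methods

## Graph construction

Input is a set {s₁…sₙ} of haplotype genome sequences with one designated
reference. Degenerate IUPAC bases are replaced by the most frequent concrete
base of the *other* samples at the same column (ties broken to the
lexicographically smallest base so output is deterministic); every
replacement is logged as (1-based position, original, replacement). The
longest repeat segment length kᵢ of each sequence is computed exactly with a
rank-doubling suffix array plus Kasai's LCP construction — "repeat" means a
substring occurring at least twice, overlapping occurrences included, which
is the reading consistent with intersecting tandem copies. With
K = max{kᵢ}, any k > K yields an acyclic graph; the default is K + 1 and a
user-supplied k ≤ K is accepted with a warning (the cycle machinery exists
for that regime).

Two random length-k ACGT segments, drawn from a seeded generator and
required to be absent from every input sequence (and distinct from each
other; up to 1000 draws before erroring), anchor the front and end of every
sample. The anchored graph then has exactly one indegree-0 and one
outdegree-0 node and each sample spells one start-to-end path. The graph is
a plain hash-map adjacency structure (node → {successor: color bitmask}),
not a succinct representation: the intended inputs are desk-scale (tens of
samples, ~10–20 kb each), where inspectability beats compression. Colors
are integer bitmasks internally; bit i is sample i in input order and the
string rendering puts sample 0 leftmost.

## Traversal and offsets

The postorder-like traversal visits a node only when all its incoming nodes
(in the traversal direction) are visited. Nodes move through four states —
unvisited, half-visited (≥1 but not all parents visited), to-be-visited
(queued, all parents visited), fully visited — and ready nodes are served
FIFO in discovery order. That tie-break is load-bearing: it fixes the visit
order, hence the cSupB discovery order, hence the tree's `order()` function.

Offsets follow pos(v) = max over incoming u of pos(u)+1 with pos(start) = 1,
the longest-path distance from the start. The reverse traversal yields
pre-offsets; final offsets are final(v) = pre(start) + 1 − pre(v), the one
subtraction formula that makes final(start) = 1 and reproduces the toy
graph's worked-example values. Final offsets matter because they shift an indel's
offset jump onto the edges *leaving* a bubble's source node (forward
direction), which is where gaps are read off during variant calling.

On a cyclic graph the traversal stalls ("finishes in advance") with a
non-empty half-visited set; a stall with an *empty* half-visited set can
only mean nodes disconnected from the source and is reported as a
construction error.

## cSupB discovery and the tree

A cSupB ⟨s, t, C⟩ must satisfy the four superbubble criteria — reachability,
matching, acyclicity, minimality — inside the subgraph induced by nodes
whose color intersects C, and both endpoints must be supernodes of that
subgraph (bubbles with fewer than two supernodes are not reported). The
brute-force checker `verify_csupb` implements the criteria literally and
serves as the oracle for the production detector.

Detection happens during the reverse traversal (the same pass that produces
pre-offsets), so downstream bubbles are discovered first. Nodes with forward
indegree > 1 enter a queue when visited; at each node s with forward
outdegree > 1 the queue is scanned from the most recent entry backwards.
A pair (s, t) matches when at least two outgoing edges of s intersect
color(t) and at least two incoming edges of t intersect color(s); the
emitted bubble's color is color(s) ∩ color(t). Scan bookkeeping:

* entries failing the matching principle are skipped without ending the scan;
* after an emission, t is removed and the scan continues iff
  color(t) ⊆ color(s), otherwise the scan stops;
* a candidate whose color is contained in a bubble already emitted at s
  during the same scan is skipped: all its samples funnel through the
  earlier bubble's sink, so the pair can never be minimal. This guard is
  exercised by the randomized suite, where every emission is re-checked
  against `verify_csupb` (1000+ bubbles across 100 random graphs).

Parenthood in the tree is containment: a bubble whose color includes every
sample is a root; any other bubble's parent is the earliest
later-discovered bubble whose node set and color both contain its own.
Color comparison alone is not sufficient — two disjoint bubbles can carry
identical colors — so the node-set test is part of the rule. Roots are
level 1 and children increment their parent's level; `order(child) <
order(parent)` holds for every edge by construction. Pairwise relations
(separation / intersection / inclusion) are classified from V₀ = V₁∩V₂ and
C₀ = C₁∩C₂ exactly as the five defining conditions state.

Simple cSupBs (exactly two source→sink paths — the minimal unit for
pairwise sample comparison) are enumerated per sample pair by walking both
paths through a bubble and pairing each divergence with its first
reconvergence, then widening the color to every sample that takes one of
the two branches.

## Variant calling

The working assumption is one variant per cSupB source node. For every
source, each out-branch gets gap = final(first node) − final(source) − 1;
substitution branches carry gap 0 and an indel of length L puts gap L on
the short side.

Pass 1 walks sources on the reference path in ascending bubble order. For
each alternate branch, Δ = gap(ref branch) − gap(alt branch) is the
alternate's length excess. Before typing, the excess already introduced by
descendant source nodes inside the branch (computed recursively from their
own gaps) is discounted; the residue types the node: Δ = 0 substitution,
Δ > 0 insertion of Δ bases, Δ < 0 deletion. When a descendant fully absorbs
the parent's gap, the parent becomes a substitution and the descendant is
hinted as the insertion carrier. This resolves nested configurations where
reading a single node's gap in isolation would misattribute an inner
insertion to the outer source. Some nested configurations are genuinely
ambiguous from topology alone (substitution-over-insertion and
insertion-over-deletion produce identical graphs); the deepest source that
can absorb the imbalance wins, and what cannot be resolved becomes type 4
("indel, unsure").

Pass 2 types the remaining sources (bubbles without the reference) in the
same ascending order, orienting indels with the hints inherited from pass 1
through the parent chain; equal-length branches are substitution candidates
and unhinted indels stay type 4. A source with no reference-containing
ancestor is typed 4 with a warning.

Reference positions: nodes on the reference path get the exact position of
their k-mer's last base (path index); other sources inherit from their
nearest reference-containing ancestor source, shifted by the final-offset
difference minus the entry branch's gap — an approximate correspondence
that is exact whenever branch lengths match. The locus transformation
spells left-anchored VCF 4.2 alleles (deletions from the reference,
insertions from an affected sample's path), drops substitution candidates
whose branch base equals the reference base at the mapped position — this
filter is why substitution-only inputs are called with precision 1.0 — and
skips alleles of 50 bp or more with a warning. Output records carry the
type code (1 substitution, 2 deletion, 3 insertion, 4 unsure) and haploid
per-sample genotypes derived from the affected color.

## Cycle handling

`detect_cycles` is the stalled traversal itself: cycles exist iff the
forward pass finishes in advance, and the half-visited set seeds interval
location. Interval location follows the stepwise scheme: force the
half-visited node u with minimal tentative offset to fully visited, resume,
and when a node v with an edge v→u is visited record the interval
[pos(u), pos(v)] (the deepest such closure is kept); a second stall means
another cycle (or an off-cycle choice) and the steps repeat — termination
is guaranteed because every round forces a node.

Cutting points: every offset in the interval gets a hash bucket of the
nodes there (a node's offset stands for its last base). An offset is type I
when a single all-sample degree-1 node sits there (a bridge — the ideal
cut), type II when the union color covers all samples but the locus is not
a bridge, type III otherwise. Thickness t is the number of distinct
(last base, color) states in the bucket — t has no canonical formal
definition, so this stand-in is documented and isolated in one function.
Adjacent offsets with identical (type, t) merge into regions scored
R = L/t, ranked by R with bridges preferred at ties; if no informative run
exists the position of minimum thickness is the fallback. The searchable
cut segment is the k-mer of the widest-color node at the region's middle
offset (a per-offset consensus string is also reported but may not occur
verbatim once offsets shift inside a forced cycle region). Each sample is
cut at the middle of its segment occurrence (the occurrence nearest the
reference cutting position when there are several), parts are re-anchored
and rebuilt per segment, and a segment that is still cyclic recurses to a
bounded depth.

## Synthetic populations

The generator emulates the benchmark conditions the method was designed
for: a uniform-random reference of mitogenome scale (default 16 569 bp) and
10 samples including the reference, each carrying configured numbers of
substitutions, deletions and insertions at uniform non-overlapping
positions (1-bp guard flanks), indel lengths uniform on [1, 49] bp,
substitution alleles uniform over the three alternatives. Everything is
deterministic per seed; the mutation stream is decorrelated from the
reference stream so that an inserted segment can never replay reference
bases and plant artificial long repeats.

What it does not emulate: real mitogenome base composition and mutational
spectra, hypervariable-region clustering, tandem repeats and large
rearrangements, or phylogenetic correlation between samples (each sample
mutates independently from the reference). Passing tests therefore show
the graph machinery is correct under the stated conditions, not that
accuracy figures transfer to arbitrary real populations — on real data,
accuracy degrades as sample similarity drops, which the k/indel trend
checks demonstrate in miniature.

Evaluation matches calls to truth by reference position: exact for
substitutions, ±1 for indels (left-anchoring ambiguity); type-mapped mode
additionally requires type agreement, with type 4 accepted for either
indel type. Precision counts matched calls, recall matched truth loci, and
tp+fp = 0 yields precision 1.0 by convention.

## Problem sizes and numerical choices

The default test run uses 100 random populations of 200–1000 bp with 2–5
samples for the brute-force property suite, 60-bp to 1-kb fixtures for the
worked variant cases, and five 16.5-kb 10-sample populations for the
substitution-only benchmark; the trend checks run 4-kb populations (5
repeats per grid point) so the whole suite stays in a few minutes on one
core. The acceptance script repeats the substitution-only benchmark five
times at full 16.5-kb scale. Anchor drawing retries up to 1000 times;
anchor k-mers recurring at junctions abort construction with advice to
re-seed. All traversal tie-breaks are FIFO on discovery order; bubble
candidates are verified lazily (`verify=True` re-checks each emission
against the brute-force oracle when wanted).

## Known limitations

* Indels ≥ 50 bp, inversions and tandem duplications are out of scope.
* The one-variant-per-source assumption breaks when sample similarity is
  low: several true variants inside one k-window collapse onto one source
  (depressing recall), and the source count falling far below the variant
  count is the method's documented failure signature.
* Reference positions of sources off the reference path are approximate in
  the presence of nearby unbalanced indels.
* Highly repetitive sequence makes cutting fragment the inputs; tandem
  repeats can defeat the cutting-point model entirely.
* The sanitization column vote assumes positional comparability across
  samples, which degrades once upstream indels shift the alignment.
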