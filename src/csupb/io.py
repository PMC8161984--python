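"""Readers and writers: FASTA input, the JSON graph bundle, the TSV dialects
(CST, CSDI, NNI, OVI, CCP), VCF 4.2 output and annotation tables.

The graph bundle is versioned JSON rather than a binary format so that every
artifact of a run stays inspectable at desk scale.  The TSV dialects keep the
file names of the original tool family; the column layouts are this
package's own and are documented in each writer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, TextIO

from Bio import SeqIO

from .cycles import CutRegion, CycleRecord
from .decompose import CSupB, CSupBTree, is_simple
from .graph import ColoredDBG, ColorSet, Genome
from .traversal import OffsetMap
from .variants import LocusVariant

BUNDLE_VERSION = 1

__all__ = [
    "read_fasta",
    "write_fasta",
    "graph_to_bundle",
    "bundle_to_graph",
    "write_ovi",
    "write_nni",
    "write_cst",
    "read_cst",
    "write_csdi",
    "write_ccp",
    "write_vcf",
    "read_vcf_records",
    "read_gtf_records",
]


# -- FASTA ------------------------------------------------------------------

def read_fasta(paths: Sequence[str | Path]) -> list[tuple[str, str]]:
    """(id, sequence) pairs from one or more FASTA files, in file order."""
    out: list[tuple[str, str]] = []
    for p in paths:
        for rec in SeqIO.parse(str(p), "fasta"):
            out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records found in {list(map(str, paths))}")
    return out


def write_fasta(genomes: Sequence[Genome], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.sample_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


# -- graph bundle -----------------------------------------------------------

def graph_to_bundle(graph: ColoredDBG, path: str | Path) -> None:
    doc = {
        "format": "csupb-graph",
        "version": BUNDLE_VERSION,
        "k": graph.k,
        "sample_ids": graph.sample_ids,
        "anchors": list(graph.anchors),
        "start_node": graph.start_node,
        "end_node": graph.end_node,
        "nodes": graph.nodes,
        "edges": [
            [u, v, c] for u, targets in graph.out_edges.items() for v, c in targets.items()
        ],
        "sample_paths": graph.sample_paths,
    }
    Path(path).write_text(json.dumps(doc))


def bundle_to_graph(path: str | Path) -> ColoredDBG:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "csupb-graph":
        raise ValueError(f"{path} is not a graph bundle")
    out_edges: dict[str, dict[str, int]] = {}
    in_edges: dict[str, dict[str, int]] = {}
    for u, v, c in doc["edges"]:
        out_edges.setdefault(u, {})[v] = c
        in_edges.setdefault(v, {})[u] = c
    return ColoredDBG(
        k=doc["k"],
        sample_ids=doc["sample_ids"],
        nodes=doc["nodes"],
        out_edges=out_edges,
        in_edges=in_edges,
        start_node=doc["start_node"],
        end_node=doc["end_node"],
        anchors=tuple(doc["anchors"]),
        sample_paths=doc["sample_paths"],
    )


# -- offset / neighborhood tables ------------------------------------------

def write_ovi(graph: ColoredDBG, offsets: OffsetMap, path: str | Path) -> None:
    """Offset value information: node, forward, pre- and final offset."""
    with open(path, "w") as fh:
        fh.write("node\tforward\tpre\tfinal\n")
        for n in sorted(graph.nodes, key=lambda n: offsets.final[n]):
            fh.write(f"{n}\t{offsets.forward[n]}\t{offsets.pre[n]}\t{offsets.final[n]}\n")


def write_nni(graph: ColoredDBG, path: str | Path) -> None:
    """Node nearby information: node, color, in-neighbors, out-neighbors."""
    with open(path, "w") as fh:
        fh.write("node\tcolor\tin_neighbors\tout_neighbors\n")
        for n in sorted(graph.nodes):
            ins = ",".join(sorted(graph.predecessors(n))) or "."
            outs = ",".join(sorted(graph.successors(n))) or "."
            fh.write(f"{n}\t{graph.color(n)}\t{ins}\t{outs}\n")


# -- cSupB tables -----------------------------------------------------------

def write_cst(tree: CSupBTree, path: str | Path) -> None:
    """cSupB topology: order, source, sink, color, parent (. for roots),
    level."""
    with open(path, "w") as fh:
        fh.write("order\tsource\tsink\tcolor\tparent\tlevel\n")
        for o in sorted(tree.bubbles):
            b = tree[o]
            parent = b.parent if b.parent is not None else "."
            fh.write(f"{o}\t{b.source}\t{b.sink}\t{b.colorset}\t{parent}\t{b.level}\n")


def read_cst(path: str | Path, graph: ColoredDBG) -> CSupBTree:
    """Round-trip reader for the CST table (node sets recomputed)."""
    from .decompose import csupb_node_set

    bubbles: dict[int, CSupB] = {}
    roots: list[int] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        o, source, sink, color, parent, level = line.split("\t")
        cs = ColorSet.from_string(color)
        b = CSupB(
            order=int(o),
            source=source,
            sink=sink,
            color=cs.bits,
            nodes=csupb_node_set(graph, source, sink, cs.bits),
            parent=None if parent == "." else int(parent),
            level=int(level),
            n_samples=graph.n_samples,
        )
        bubbles[b.order] = b
        if b.parent is None:
            roots.append(b.order)
    for b in bubbles.values():
        if b.parent is not None:
            bubbles[b.parent].children.append(b.order)
    return CSupBTree(bubbles=bubbles, roots=sorted(roots))


def write_csdi(graph: ColoredDBG, tree: CSupBTree, path: str | Path) -> None:
    """cSupB detailed information: per bubble, node/edge/branch/supernode
    counts, per-sample path lengths and branch composition."""
    with open(path, "w") as fh:
        fh.write(
            "order\tnodes\tedges\tbranches\tsupernodes\tsimple\t"
            "sample_lengths\tbranch_heads\n"
        )
        for o in sorted(tree.bubbles):
            b = tree[o]
            nset = b.nodes
            n_edges = sum(
                1
                for u in nset
                for v in graph.successors(u)
                if v in nset and u != b.sink
            )
            supers = sum(1 for n in nset if graph.is_supernode(n))
            heads = sorted(graph.successors(b.source))
            lengths = []
            for i in b.colorset.samples():
                p = graph.sample_paths[graph.sample_ids[i]]
                try:
                    lengths.append(str(p.index(b.sink) - p.index(b.source)))
                except ValueError:
                    lengths.append(".")
            fh.write(
                f"{o}\t{len(nset)}\t{n_edges}\t{len(heads)}\t{supers}\t"
                f"{int(is_simple(graph, b))}\t{','.join(lengths)}\t{','.join(heads)}\n"
            )


def write_ccp(
    records: Sequence[tuple[int, CycleRecord, CutRegion]], path: str | Path
) -> None:
    """Cycle cut position: cycle id, interval, chosen region, type, R,
    reference cut position and region bases."""
    with open(path, "w") as fh:
        fh.write(
            "cycle\tcycle_start_pos\tcycle_end_pos\tregion_start\tregion_end\t"
            "type\tL\tt\tR\treference_cut_pos\tbases\n"
        )
        for cid, rec, region in records:
            fh.write(
                f"{cid}\t{rec.cycle_start_pos}\t{rec.cycle_end_pos}\t"
                f"{region.interval[0]}\t{region.interval[1]}\t{region.point_type}\t"
                f"{region.L}\t{region.t}\t{region.R:g}\t"
                f"{region.reference_cut_pos}\t{region.bases or '.'}\n"
            )


# -- VCF --------------------------------------------------------------------

def write_vcf(
    variants: Sequence[LocusVariant],
    graph: ColoredDBG,
    ref_id: str,
    path: str | Path,
    contig: Optional[str] = None,
) -> None:
    """Minimal VCF 4.2: one record per locus variant, 1-based positions,
    left-anchored indels, INFO VARTYPE carrying the 1/2/3/4 type code, and a
    haploid GT column per sample derived from the affected color."""
    contig = contig or ref_id
    samples = graph.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            '##INFO=<ID=VARTYPE,Number=1,Type=Integer,Description='
            '"1 substitution, 2 deletion, 3 insertion, 4 indel unsure">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            gts = "\t".join(
                "1" if v.affected_color >> i & 1 else "0" for i in range(len(samples))
            )
            fh.write(
                f"{contig}\t{v.refpos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t"
                f"VARTYPE={v.vartype}\tGT\t{gts}\n"
            )


def read_vcf_records(path: str | Path) -> list[dict]:
    """Light positional view of a VCF (pysam-backed): chrom, pos, ref, alts."""
    from pysam import VariantFile

    out = []
    with VariantFile(str(path)) as vf:
        for rec in vf:
            out.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alts": list(rec.alts or ()),
                }
            )
    return out


def read_gtf_records(path: str | Path) -> list[dict]:
    """9-column GTF/GFF features as dicts with 1-based inclusive coords."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GTF line: {line[:80]!r}")
        out.append(
            {
                "seqname": f[0],
                "feature": f[2],
                "start": int(f[3]),
                "end": int(f[4]),
                "strand": f[6],
                "attributes": f[8],
            }
        )
    return out
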