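"""Node-based variant detection: gaps, NVD typing, RPD and locus records."""

import numpy as np
import pytest

from csupb.decompose import build_csupb_tree, find_csupbs
from csupb.graph import Genome, build_graph, generate_anchors
from csupb.pipeline import run_pipeline
from csupb.traversal import final_offsets
from csupb.variants import (
    DEL,
    INS,
    SUB,
    collect_gaps,
    call_variants,
    node_to_locus,
    rpd,
)

REF60 = "".join(np.random.default_rng(7).choice(list("ACGT"), size=60))


def pipeline(seqs, ref_id="R", k=8, seed=2):
    return run_pipeline(seqs, ref_id, k=k, seed=seed)


class TestGaps:
    def test_substitution_bubble_has_zero_gaps(self):
        alt = REF60[:30] + ("A" if REF60[30] != "A" else "C") + REF60[31:]
        res = pipeline([("R", REF60), ("S", alt)])
        gaps = collect_gaps(res.graph, res.offsets, res.tree)
        assert gaps
        for gi in gaps.values():
            assert all(gap == 0 for _, gap, _ in gi.branches)

    def test_one_bp_deletion_gap_on_deleted_branch(self):
        alt = REF60[:30] + REF60[31:]
        res = pipeline([("R", REF60), ("D", alt)])
        gaps = collect_gaps(res.graph, res.offsets, res.tree)
        (gi,) = gaps.values()
        by_gap = {gap: col for col, gap, _ in gi.branches}
        assert sorted(by_gap) == [0, 1]
        # the deleted sample (bit 1) sits on the gapped branch
        assert by_gap[1] == 0b10
        assert gi.max_gap == 1

    def test_gaps_attach_at_source_not_sink(self, toy_graph, toy_offsets, toy_tree):
        gaps = collect_gaps(toy_graph, toy_offsets, toy_tree)
        # the insertion's length jump is visible at TCA (the source), and
        # the sink-side source GGG carries no gap
        assert gaps["TCA"].max_gap == 1
        assert gaps["GGG"].max_gap == 0


class TestTyping:
    def test_both_gaps_zero_is_substitution(self):
        alt = REF60[:30] + ("A" if REF60[30] != "A" else "C") + REF60[31:]
        res = pipeline([("R", REF60), ("S", alt)])
        assert {v.vartype for v in res.node_variants} == {SUB}

    def test_three_bp_deletion_typed_with_alt_color(self):
        alt = REF60[:30] + REF60[33:]
        res = pipeline([("R", REF60), ("D", alt)])
        dels = [v for v in res.node_variants if v.vartype == DEL]
        assert len(dels) == 1
        assert dels[0].length == 3
        assert dels[0].affected_color == 0b10

    def test_insertion_typed_from_reference_branch_gap(self):
        alt = REF60[:30] + "TTACG" + REF60[30:]
        res = pipeline([("R", REF60), ("I", alt)])
        ins = [v for v in res.node_variants if v.vartype == INS]
        assert len(ins) == 1 and ins[0].length == 5

    def test_nested_snp_under_insertion(self):
        # R lacks the insert; X and Y carry it, differing by one base inside:
        # the outer source is an insertion, the inner source a substitution
        res = pipeline(
            [
                ("R", REF60),
                ("X", REF60[:30] + "ACGTTGCAAT" + REF60[30:]),
                ("Y", REF60[:30] + "ACGTAGCAAT" + REF60[30:]),
            ],
            k=8,
            seed=3,
        )
        types = sorted(v.vartype for v in res.node_variants)
        assert types == [SUB, SUB, INS] or types == [SUB, INS]
        outer = [v for v in res.node_variants if v.vartype == INS]
        assert outer[0].length == 10
        assert outer[0].affected_color == 0b110

    def test_nonreference_substitution_typed_via_parent_chain(self):
        # three different bases at one site: the X-vs-Y divergence lives in a
        # cSupB without the reference and is typed in the second pass
        base = REF60[30]
        others = [b for b in "ACGT" if b != base]
        res = pipeline(
            [
                ("R", REF60),
                ("X", REF60[:30] + others[0] + REF60[31:]),
                ("Y", REF60[:30] + others[1] + REF60[31:]),
            ],
            k=8,
            seed=3,
        )
        locus = res.locus_variants
        assert {(v.refpos, v.alt_allele) for v in locus} == {
            (31, others[0]),
            (31, others[1]),
        }
        assert all(v.vartype == SUB for v in locus)


class TestRPD:
    def test_reference_path_positions_are_exact(self):
        alt = REF60[:30] + REF60[31:]
        res = pipeline([("R", REF60), ("D", alt)])
        refmap = rpd(res.graph, res.tree, res.offsets, "R")
        path = res.graph.sample_paths["R"]
        for i, node in enumerate(path):
            assert refmap[node] == i

    def test_nonreference_source_inherits_from_ancestor(self):
        # X and Y share one substitution, then diverge from each other within
        # the k-window: that second divergence's source is off the reference
        # path and inherits its position from the reference-containing parent
        shared = "A" if REF60[27] != "A" else "T"
        base = REF60[30]
        others = [b for b in "ACGT" if b != base]
        stem = REF60[:27] + shared + REF60[28:]
        res = pipeline(
            [
                ("R", REF60),
                ("X", stem[:30] + others[0] + stem[31:]),
                ("Y", stem[:30] + others[1] + stem[31:]),
            ],
            k=8,
            seed=3,
        )
        refmap = rpd(res.graph, res.tree, res.offsets, "R")
        ref_bit = 1
        offpath = [
            s
            for s in refmap
            if not res.graph.nodes.get(s, 0) & ref_bit and s in res.graph.nodes
        ]
        assert offpath
        # the off-path source diverges inside the k-window of position 31
        for s in offpath:
            assert 24 <= refmap[s] <= 31


class TestLocus:
    def test_no_variants_yields_empty_list(self):
        res = pipeline([("R", REF60), ("S", REF60)], k=8, seed=4)
        assert res.locus_variants == []

    def test_snp_record_matches_manual_alignment(self):
        alt_base = "A" if REF60[30] != "A" else "C"
        alt = REF60[:30] + alt_base + REF60[31:]
        res = pipeline([("R", REF60), ("S", alt)])
        (v,) = res.locus_variants
        assert (v.refpos, v.ref_allele, v.alt_allele, v.vartype) == (
            31,
            REF60[30],
            alt_base,
            SUB,
        )
        assert v.affected_color == 0b10

    def test_deletion_record_left_anchored(self):
        alt = REF60[:30] + REF60[33:]
        res = pipeline([("R", REF60), ("D", alt)])
        (v,) = res.locus_variants
        assert v.refpos == 30
        assert v.ref_allele == REF60[29:33]
        assert v.alt_allele == REF60[29]

    def test_insertion_record_spells_inserted_bases(self):
        alt = REF60[:30] + "TTACG" + REF60[30:]
        res = pipeline([("R", REF60), ("I", alt)])
        (v,) = res.locus_variants
        assert (v.refpos, v.ref_allele, v.alt_allele) == (30, REF60[29], REF60[29] + "TTACG")

    def test_large_indels_skipped_with_warning(self):
        ref = "".join(np.random.default_rng(9).choice(list("ACGT"), size=300))
        ins = "".join(np.random.default_rng(10).choice(list("ACGT"), size=60))
        alt = ref[:150] + ins + ref[150:]
        with pytest.warns(UserWarning, match="small-indel"):
            res = pipeline([("R", ref), ("I", alt)], k=10, seed=5)
        assert res.locus_variants == []

    def test_calls_sorted_by_reference_position(self):
        rng = np.random.default_rng(12)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        alt = list(ref)
        for p in (50, 150, 300):
            alt[p] = "A" if alt[p] != "A" else "G"
        res = pipeline([("R", ref), ("S", "".join(alt))], k=10, seed=6)
        pos = [v.refpos for v in res.locus_variants]
        assert pos == sorted(pos) == [51, 151, 301]


class TestRoundTrip:
    def test_few_isolated_variants_recovered_exactly(self):
        # <=3 isolated events on a 1-kb reference: calls equal truth exactly
        rng = np.random.default_rng(21)
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        alt = list(ref)
        alt[100] = "A" if alt[100] != "A" else "G"   # SNP at 101
        alt = "".join(alt)
        alt = alt[:400] + alt[403:]                  # 3-bp deletion at 400
        alt = alt[:700] + "GTCA" + alt[700:]         # 4-bp insertion at 700+3 shift
        res = pipeline([("R", ref), ("S", alt)], k=12, seed=7)
        got = {(v.refpos, v.vartype) for v in res.locus_variants}
        assert got == {(101, SUB), (400, DEL), (703, INS)}

    def test_source_count_tracks_variant_count_on_sparse_data(self):
        # one source node per isolated variant (the one-to-one assumption)
        rng = np.random.default_rng(22)
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        alt = list(ref)
        for p in (100, 400, 700):
            alt[p] = "A" if alt[p] != "A" else "G"
        res = pipeline([("R", ref), ("S", "".join(alt))], k=12, seed=8)
        sources = {v.source for v in res.node_variants}
        assert len(sources) == 3
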