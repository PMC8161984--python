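"""Shared fixtures: the worked three-sample toy graph and random populations.

The toy reproduces a fully worked example: three short haplotypes whose
k=3 colored de Bruijn graph contains five cSupBs discovered in a known
order, with known final offsets, parentage and coordinate tuples.  All
expected values in the tests that use it were derived by hand from the
graph (and cross-checked against the brute-force bubble checker).
"""

from __future__ import annotations

import numpy as np
import pytest

from csupb.decompose import build_csupb_tree, find_csupbs
from csupb.graph import Genome, build_graph, generate_anchors, sanitize_genomes
from csupb.simulate import SimConfig, random_reference, simulate_population
from csupb.traversal import final_offsets

# three haplotypes, k = 3, fixed anchors: the worked toy graph
TOY_SEQS = [
    ("s1", "CAGGGTGTATGACCC"),
    ("s2", "CACGGGAGTATAACCC"),
    ("s3", "CACTTCCGTATAACCC"),
]
TOY_ANCHORS = ("GAT", "ATT")
TOY_K = 3


@pytest.fixture(scope="session")
def toy_genomes():
    return [Genome(sid, seq) for sid, seq in TOY_SEQS]


@pytest.fixture(scope="session")
def toy_graph(toy_genomes):
    return build_graph(toy_genomes, TOY_K, TOY_ANCHORS)


@pytest.fixture(scope="session")
def toy_offsets(toy_graph):
    return final_offsets(toy_graph)


@pytest.fixture(scope="session")
def toy_csupbs(toy_graph):
    return find_csupbs(toy_graph)


@pytest.fixture(scope="session")
def toy_tree(toy_csupbs):
    return build_csupb_tree(toy_csupbs)


def make_population(
    seed: int,
    length: int = 500,
    n_samples: int = 3,
    snp: int = 3,
    dele: int = 0,
    ins: int = 0,
    indel_len: tuple[int, int] = (1, 8),
):
    """A small simulated population plus its truth set."""
    ref = random_reference(length, seed=seed)
    cfg = SimConfig(
        n_samples=n_samples,
        snp_count=snp,
        del_count=dele,
        ins_count=ins,
        indel_len_range=indel_len,
        seed=seed,
    )
    return simulate_population(ref, cfg)


def build_random_graph(seed: int, k: int = 15, **kw):
    """A sanitized, anchored colored dBG over a random small population."""
    genomes, truth = make_population(seed, **kw)
    genomes = sanitize_genomes([(g.sample_id, g.sequence) for g in genomes])
    anchors = generate_anchors(k, genomes, seed=seed)
    return build_graph(genomes, k, anchors), genomes, truth


def to_networkx(graph):
    """Independent-oracle view of a ColoredDBG as a networkx DiGraph."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u, targets in graph.out_edges.items():
        for v in targets:
            g.add_edge(u, v)
    return g


def longest_path_offsets(graph):
    """Longest-path distances from the start node by an independent DP over
    a networkx topological order (the offsets oracle)."""
    import networkx as nx

    g = to_networkx(graph)
    dist = {n: None for n in graph.nodes}
    dist[graph.start_node] = 1
    for u in nx.topological_sort(g):
        if dist[u] is None:
            continue
        for v in g.successors(u):
            if dist[v] is None or dist[v] < dist[u] + 1:
                dist[v] = dist[u] + 1
    return dist
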