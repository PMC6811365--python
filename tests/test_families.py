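"""Similarity network, greedy set cover, profile comparison and MCL."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phagehost.families import (
    align_members,
    build_families,
    build_network,
    compare_subfamilies,
    core_families,
    families_from_clusters,
    greedy_set_cover,
    mcl,
)
from phagehost.simulate.proteome import mutate_protein, random_protein


# ---------------------------------------------------------------------------
# independent oracles


def oracle_greedy_cover(graph):
    """Straightforward reimplementation of the documented greedy rule."""
    uncovered = set(graph.nodes)
    covers = []
    while uncovered:
        candidates = []
        for node in uncovered:
            nbrs = {v for v in graph.neighbors(node)} & uncovered
            score = sum(graph[node][v].get("score", 1.0) for v in nbrs)
            candidates.append((-len(nbrs), -score, node, nbrs))
        candidates.sort()
        _, _, rep, nbrs = candidates[0]
        covers.append((rep, frozenset(nbrs | {rep})))
        uncovered -= nbrs | {rep}
    return covers


def brute_force_min_dominating(graph):
    """Smallest set of nodes whose closed neighborhoods cover the graph."""
    nodes = list(graph.nodes)
    for k in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, k):
            covered = set()
            for c in combo:
                covered.add(c)
                covered.update(graph.neighbors(c))
            if covered == set(nodes):
                return k
    return len(nodes)


def oracle_mcl_partition(graph, inflation=2.0, prune=1e-4, max_iter=200,
                         eps=1e-6):
    """Loop-based Markov Clustering with the same published recipe."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = [[0.0] * n for _ in range(n)]
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        M[idx[u]][idx[v]] = w
        M[idx[v]][idx[u]] = w
    for i in range(n):
        incident = max(M[i][j] for j in range(n)) if n > 1 else 0.0
        M[i][i] = incident if incident > 0 else 1.0
    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s:
                for i in range(n):
                    mat[i][j] /= s
    normalize(M)
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        M = [[x ** inflation if x ** inflation >= 0 else 0 for x in row]
             for row in sq]
        M = [[0.0 if x < prune else x for x in row] for row in M]
        normalize(M)
        delta = max(abs(M[i][j] - prev[i][j])
                    for i in range(n) for j in range(n))
        if delta < eps:
            break
    clusters = []
    for i in range(n):
        if M[i][i] > 1e-8:
            clusters.append({nodes[j] for j in range(n) if M[i][j] > 1e-8})
    merged = []
    for c in clusters:
        for m in merged:
            if m & c:
                m |= c
                break
        else:
            merged.append(set(c))
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(merged)), 2):
            if merged[a] & merged[b]:
                merged[a] |= merged.pop(b)
                changed = True
                break
    return {frozenset(m) for m in merged}


def random_weighted_graph(seed, n_nodes=10, p=0.35):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.2, 1)))
    return g


# ---------------------------------------------------------------------------


class TestBuildNetwork:
    def test_identical_proteins_connected_at_full_coverage(self):
        p = random_protein(100, np.random.default_rng(0))
        g = build_network({"a": p, "b": p})
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["qcov"] == pytest.approx(1.0)

    def test_low_coverage_hit_filtered(self):
        hits = pd.DataFrame([("a", "b", 1e-10, 0.4, 0.9, 100.0)],
                            columns=["query", "target", "evalue", "qcov",
                                     "tcov", "score"])
        g = build_network({"a": "MKV" * 30, "b": "MKV" * 30}, hits=hits)
        assert g.number_of_edges() == 0

    def test_unrelated_random_proteins_unconnected(self):
        rng = np.random.default_rng(1)
        prots = {f"p{i}": random_protein(150, rng) for i in range(6)}
        g = build_network(prots)
        assert g.number_of_edges() == 0

    def test_unknown_hit_ids_rejected(self):
        hits = pd.DataFrame([("a", "zz", 0.0, 1, 1, 10.0)],
                            columns=["query", "target", "evalue", "qcov",
                                     "tcov", "score"])
        with pytest.raises(ValueError):
            build_network({"a": "MKVMKV"}, hits=hits)


class TestGreedySetCover:
    def test_star_graph_single_subfamily_with_hub_rep(self):
        g = nx.star_graph(5)
        subs = greedy_set_cover(g)
        assert len(subs) == 1
        assert subs[0].representative == 0

    def test_two_cliques_two_subfamilies(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        subs = greedy_set_cover(g)
        assert len(subs) == 2
        assert sorted(len(s.members) for s in subs) == [3, 4]

    def test_partition_property(self):
        g = random_weighted_graph(7, n_nodes=15)
        subs = greedy_set_cover(g)
        seen = [m for s in subs for m in s.members]
        assert sorted(seen) == sorted(g.nodes)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_greedy_and_ln_bound(self, seed):
        g = random_weighted_graph(seed, n_nodes=8, p=0.4)
        subs = greedy_set_cover(g)
        oracle = oracle_greedy_cover(g)
        assert [(s.representative, frozenset(s.members)) for s in subs] == \
            [(rep, members) for rep, members in oracle]
        opt = brute_force_min_dominating(g)
        max_deg = max((d for _, d in g.degree), default=0)
        harmonic = sum(1.0 / k for k in range(1, max_deg + 2))
        assert len(subs) <= math.ceil(opt * harmonic)


class TestCompareSubfamilies:
    def _subfam_pair_from_parent(self, seed, divergence=0.1):
        rng = np.random.default_rng(seed)
        parent = random_protein(160, rng)
        prots = {}
        for tag in ("a", "b"):
            for i in range(3):
                pid = f"{tag}{i}"
                prots[pid] = mutate_protein(parent, int(divergence * 160), rng)
        net = build_network(prots)
        # force two subfamilies by splitting the ids
        from phagehost.families import Subfamily

        sf1 = Subfamily("subfam_a", "a0", ["a0", "a1", "a2"])
        sf2 = Subfamily("subfam_b", "b0", ["b0", "b1", "b2"])
        align_members(sf1, prots)
        align_members(sf2, prots)
        return sf1, sf2, prots

    def test_duplicated_subfamily_scores_like_self(self):
        sf1, sf2, _ = self._subfam_pair_from_parent(0, divergence=0.0)
        g = compare_subfamilies([sf1, sf2])
        assert g.has_edge("subfam_a", "subfam_b")
        e = g["subfam_a"]["subfam_b"]
        assert e["probability"] > 0.99
        assert e["coverage"] == pytest.approx(1.0)
        assert e["weight"] == pytest.approx(e["probability"] * e["coverage"])

    def test_diverged_relatives_still_linked(self):
        sf1, sf2, _ = self._subfam_pair_from_parent(1, divergence=0.25)
        g = compare_subfamilies([sf1, sf2])
        assert g.has_edge("subfam_a", "subfam_b")

    def test_unrelated_subfamilies_stay_unlinked(self):
        from phagehost.families import Subfamily

        rng = np.random.default_rng(2)
        subs = []
        prots = {}
        for i in range(5):
            pid = f"u{i}"
            prots[pid] = random_protein(150, rng)
            sf = Subfamily(f"subfam_{i}", pid, [pid])
            align_members(sf, prots)
            subs.append(sf)
        g = compare_subfamilies(subs)
        assert g.number_of_edges() == 0

    def test_missing_alignment_is_error(self):
        from phagehost.families import Subfamily

        sf = Subfamily("s", "x", ["x"])
        with pytest.raises(ValueError):
            compare_subfamilies([sf])


class TestMCL:
    def test_two_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        clusters, converged = mcl(g)
        assert converged
        assert sorted(len(c) for c in clusters) == [4, 5]

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("only")
        clusters, _ = mcl(g)
        assert clusters == [frozenset({"only"})]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_implementation(self, seed):
        g = random_weighted_graph(seed, n_nodes=11, p=0.3)
        clusters, _ = mcl(g)
        expected = oracle_mcl_partition(g)
        assert {frozenset(c) for c in clusters} == expected

    def test_partition_is_total_and_disjoint(self):
        g = random_weighted_graph(42, n_nodes=14, p=0.25)
        clusters, _ = mcl(g)
        flat = [v for c in clusters for v in c]
        assert sorted(flat) == sorted(g.nodes)

    def test_invariance_to_relabeling_and_scaling(self):
        g = random_weighted_graph(5, n_nodes=9, p=0.4)
        base, _ = mcl(g)
        mapping = {v: f"x_{v}" for v in g.nodes}
        relabeled, _ = mcl(nx.relabel_nodes(g, mapping))
        assert {frozenset(mapping[v] for v in c) for c in base} == \
            set(relabeled)
        scaled = g.copy()
        for u, v in scaled.edges:
            scaled[u][v]["weight"] *= 7.3
        rescaled, _ = mcl(scaled)
        assert set(base) == set(rescaled)

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError):
            mcl(g)


class TestCoreFamilies:
    def _family_set(self, presence_rows, genomes):
        from phagehost.families import FamilySet

        presence = pd.DataFrame(presence_rows, columns=genomes)
        return FamilySet(families=[frozenset({f"s{i}"})
                                   for i in range(len(presence_rows))],
                         protein_family=pd.Series(dtype=int),
                         presence=presence)

    def test_ubiquitous_family_is_core(self):
        fs = self._family_set([[True] * 5], [f"g{i}" for i in range(5)])
        assert core_families(fs) == [0]

    def test_two_of_28_missing_needs_slack(self):
        genomes = [f"g{i}" for i in range(28)]
        row = [i >= 2 for i in range(28)]  # missing from 2 genomes
        fs = self._family_set([row], genomes)
        assert core_families(fs, slack=0.0) == []
        assert core_families(fs, slack=2 / 28) == [0]

    def test_planted_pan_genome_core_recovered(self):
        rng = np.random.default_rng(3)
        core_anc = [random_protein(130, rng) for _ in range(3)]
        acc_anc = [random_protein(130, rng) for _ in range(2)]
        prots, gmap = {}, {}
        for g in range(5):
            for f, anc in enumerate(core_anc):
                pid = f"g{g}_c{f}"
                prots[pid] = mutate_protein(anc, 20, rng)
                gmap[pid] = f"genome_{g}"
            for f, anc in enumerate(acc_anc):
                if g % 2 == 0:  # accessory: only in some genomes
                    pid = f"g{g}_a{f}"
                    prots[pid] = mutate_protein(anc, 20, rng)
                    gmap[pid] = f"genome_{g}"
        fs = build_families(prots, gmap, seed=3)
        core = core_families(fs)
        assert len(core) == 3
        acc = [i for i in fs.presence.index if i not in core]
        assert all(fs.presence.loc[i].sum() == 3 for i in acc)
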