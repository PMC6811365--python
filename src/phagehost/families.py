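"""Protein families for comparative phage genomics.

The pipeline mirrors the standard comparative-genomics recipe: an
all-versus-all protein similarity search filtered at E <= 1e-3 and mutual
coverage >= 0.5 builds a similarity network; a greedy set cover collapses
it into *subfamilies* (representative + neighbors); subfamilies are then
compared to each other through their alignment column profiles to catch
distant homology, and pairs scoring above a calibrated probability-like
threshold (>= 0.95, coverage >= 0.5; edge weight = probability x
coverage) feed Markov Clustering (inflation 2.0), whose clusters are the
*families*. Families present in (essentially) every genome of a set are
its core families.

The profile-comparison step replaces HMM-HMM search with profile-profile
dynamic programming: raw alignment scores are standardized against
column-shuffled nulls and squashed through a fixed logistic, which makes
the >= 0.95 filter reproducible without external tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from ._dp import AA_ORDER, BLOSUM62, profile_align

logger = logging.getLogger(__name__)

__all__ = [
    "Subfamily",
    "FamilySet",
    "build_network",
    "greedy_set_cover",
    "align_members",
    "compare_subfamilies",
    "mcl",
    "families_from_clusters",
    "core_families",
    "build_families",
]

# Karlin-Altschul constants for gapped BLOSUM62 with gap 11/1 (BLAST's
# tabulated values); used by the internal aligner's E-value approximation.
KA_LAMBDA = 0.267
KA_K = 0.041

_N_AA = 20  # profile columns use the 20 standard residues
_B20 = BLOSUM62[:_N_AA, :_N_AA].astype(float)


def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    al.mode = mode
    al.open_gap_score = -12
    al.extend_gap_score = -1
    if mode == "global":
        try:
            al.end_insertion_score = 0.0
            al.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            al.target_end_gap_score = 0.0
            al.query_end_gap_score = 0.0
    return al


def build_network(proteins: dict[str, str], hits: pd.DataFrame | None = None,
                  evalue_max: float = 1e-3, min_cover: float = 0.5,
                  ) -> nx.Graph:
    """Similarity network over proteins.

    ``hits`` (columns query, target, evalue, qcov, tcov, score) is consumed
    as-is when supplied; otherwise all-versus-all Smith-Waterman (BLOSUM62,
    gap 11/1) with a Karlin-Altschul E-value approximation is run —
    intended for desk-scale inputs (<= ~2000 proteins). Edges keep pairs
    with E <= evalue_max and min(qcov, tcov) >= min_cover; self-hits drop.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    if hits is None:
        hits = _all_vs_all(proteins)
    else:
        unknown = (set(hits["query"]) | set(hits["target"])) - set(proteins)
        if unknown:
            raise ValueError(f"hit ids absent from protein set: {sorted(unknown)[:5]}")
    for row in hits.itertuples():
        if row.query == row.target:
            continue
        if row.evalue > evalue_max or min(row.qcov, row.tcov) < min_cover:
            continue
        prev = g.get_edge_data(row.query, row.target)
        if prev is None or row.score > prev["score"]:
            g.add_edge(row.query, row.target, evalue=float(row.evalue),
                       qcov=float(row.qcov), tcov=float(row.tcov),
                       score=float(row.score))
    return g


def _all_vs_all(proteins: dict[str, str]) -> pd.DataFrame:
    if len(proteins) > 2000:
        raise ValueError("internal all-vs-all is desk-scale only (<= 2000)")
    al = _aligner("local")
    ids = sorted(proteins)
    rows = []
    for i, q in enumerate(ids):
        for t in ids[i + 1:]:
            aln = al.align(proteins[q], proteins[t])
            score = float(aln.score)
            best = aln[0]
            (qs, qe) = best.aligned[0][0][0], best.aligned[0][-1][1]
            (ts, te) = best.aligned[1][0][0], best.aligned[1][-1][1]
            m, n = len(proteins[q]), len(proteins[t])
            evalue = KA_K * m * n * np.exp(-KA_LAMBDA * score)
            rows.append((q, t, evalue, (qe - qs) / m, (te - ts) / n, score))
    return pd.DataFrame(rows, columns=["query", "target", "evalue", "qcov",
                                       "tcov", "score"])


@dataclass
class Subfamily:
    id: str
    representative: str
    members: list[str]
    alignment: list[str] | None = None  # rows on representative coordinates


def greedy_set_cover(graph: nx.Graph) -> list[Subfamily]:
    """Greedy set cover: repeatedly take the node covering most uncovered.

    Ties break by higher summed edge score over uncovered neighbors, then
    lexicographic id. Singletons are allowed. Subfamilies partition the
    node set.
    """
    uncovered = set(graph.nodes)
    out: list[Subfamily] = []
    while uncovered:
        best = None
        best_key = None
        for node in sorted(uncovered):
            nbrs = [v for v in graph.neighbors(node) if v in uncovered]
            score = sum(graph[node][v].get("score", 1.0) for v in nbrs)
            key = (-len(nbrs), -score, node)
            if best_key is None or key < best_key:
                best, best_key = (node, nbrs), key
        rep, nbrs = best
        members = sorted([rep] + nbrs)
        out.append(Subfamily(id=f"subfam_{len(out):04d}", representative=rep,
                             members=members))
        uncovered -= set(members)
    return out


def align_members(subfamily: Subfamily, proteins: dict[str, str]) -> Subfamily:
    """Star alignment of members onto representative coordinates.

    Each member is globally aligned to the representative; member residues
    aligned to representative columns are kept, insertions relative to the
    representative are dropped. Rows therefore share the representative's
    length — adequate for column frequency profiles.
    """
    rep_seq = proteins[subfamily.representative]
    al = _aligner("global")
    rows = []
    for m in subfamily.members:
        if m == subfamily.representative:
            rows.append(rep_seq)
            continue
        best = al.align(rep_seq, proteins[m])[0]
        row = ["-"] * len(rep_seq)
        for (rs, re), (ms, me) in zip(best.aligned[0], best.aligned[1]):
            seg = proteins[m][ms:me]
            for k, aa in enumerate(seg):
                row[rs + k] = aa
        rows.append("".join(row))
    subfamily.alignment = rows
    return subfamily


def _profile(subfamily: Subfamily, pseudocount: float = 0.02) -> np.ndarray:
    if not subfamily.alignment:
        raise ValueError(f"subfamily {subfamily.id} has no alignment")
    idx = {a: i for i, a in enumerate(AA_ORDER[:_N_AA])}
    L = len(subfamily.alignment[0])
    F = np.full((L, _N_AA), pseudocount)
    for row in subfamily.alignment:
        for i, aa in enumerate(row):
            j = idx.get(aa)
            if j is not None:
                F[i, j] += 1.0
    return F / F.sum(axis=1, keepdims=True)


def _calibrated_prob(score: float, null_scores: np.ndarray,
                     z_mid: float = 8.0) -> float:
    mu = float(null_scores.mean())
    sd = float(null_scores.std())
    if sd <= 0:
        sd = 1.0
    z = (score - mu) / sd
    return float(1.0 / (1.0 + np.exp(-(z - z_mid))))


def compare_subfamilies(subfamilies: list[Subfamily], prob_min: float = 0.95,
                        cover_min: float = 0.5, gap: float = 2.0,
                        n_null: int = 30, seed: int = 0) -> nx.Graph:
    """Profile-profile comparison; edges = prob x coverage weights.

    For each subfamily pair the column-frequency profiles are aligned
    semi-globally over a BLOSUM62 column-score matrix; the raw score is
    standardized against ``n_null`` column-shuffled alignments of the same
    pair and squashed through a fixed logistic into a probability-like
    score. Pairs with probability >= prob_min and mutual coverage >=
    cover_min get an edge weighted probability x min-coverage.
    """
    rng = np.random.default_rng(seed)
    profiles = {sf.id: _profile(sf) for sf in subfamilies}
    g = nx.Graph()
    g.add_nodes_from(p.id for p in subfamilies)
    ids = sorted(profiles)
    for i, qa in enumerate(ids):
        Fq = profiles[qa]
        for tb in ids[i + 1:]:
            Ft = profiles[tb]
            S = Fq @ _B20 @ Ft.T
            score, i0, i1, j0, j1 = profile_align(S, gap)
            cov_q = (i1 - i0) / S.shape[0]
            cov_t = (j1 - j0) / S.shape[1]
            nulls = np.empty(n_null)
            for k in range(n_null):
                Sp = S[rng.permutation(S.shape[0])][:, rng.permutation(S.shape[1])]
                nulls[k], *_ = profile_align(Sp, gap)
            prob = _calibrated_prob(score, nulls)
            if prob >= prob_min and min(cov_q, cov_t) >= cover_min:
                g.add_edge(qa, tb, weight=prob * min(cov_q, cov_t),
                           probability=prob, coverage=min(cov_q, cov_t))
    return g


# ---------------------------------------------------------------------------
# Markov Clustering


def mcl(graph: nx.Graph, inflation: float = 2.0, prune: float = 1e-4,
        max_iter: int = 200, eps: float = 1e-6,
        ) -> tuple[list[frozenset], bool]:
    """Markov Clustering on a non-negative weighted graph.

    Self-loops are set to each node's maximum incident weight (1 for
    isolated nodes); iterations alternate expansion (matrix square) and
    inflation (elementwise power + column renormalization) with pruning of
    entries below ``prune``. Returns (clusters, converged). Overlapping
    attractor systems are merged; every node joins the cluster receiving
    its largest flow (ties: lexicographically first).
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return [], True
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("negative edge weight")
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    loop = M.max(axis=0)
    loop[loop <= 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < eps:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter", stacklevel=2)
    attractors = np.flatnonzero(np.diag(M) > 1e-8)
    parent = {int(i): int(i) for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    support = {int(i): np.flatnonzero(M[i] > 1e-8) for i in attractors}
    for i in attractors:
        for j in attractors:
            if i < j and np.intersect1d(support[int(i)], support[int(j)]).size:
                parent[find(int(i))] = find(int(j))
    groups: dict[int, set[int]] = {}
    for i in attractors:
        groups.setdefault(find(int(i)), set()).add(int(i))
    clusters = []
    for root, members in sorted(groups.items()):
        nodeset = set()
        for i in members:
            nodeset.update(int(j) for j in support[i])
        clusters.append(nodeset)
    # assign every node to the cluster with the largest inbound flow
    assignment: dict[int, int] = {}
    for j in range(n):
        best_c, best_flow = None, -1.0
        for ci, nodeset in enumerate(clusters):
            flow = float(M[sorted(nodeset), j].sum())
            if flow > best_flow + 1e-15:
                best_c, best_flow = ci, flow
        if best_c is None or best_flow <= 0:
            clusters.append({j})
            best_c = len(clusters) - 1
        assignment[j] = best_c
    final: dict[int, set] = {}
    for j, c in assignment.items():
        final.setdefault(c, set()).add(nodes[j])
    return [frozenset(s) for _, s in sorted(final.items())], converged


# ---------------------------------------------------------------------------
# families and core genes


@dataclass
class FamilySet:
    families: list[frozenset]  # of subfamily ids
    protein_family: pd.Series  # protein id -> family index
    presence: pd.DataFrame  # family index x genome id (bool)
    converged: bool = True
    subfamilies: list[Subfamily] = field(default_factory=list)


def families_from_clusters(clusters: list[frozenset],
                           subfamilies: list[Subfamily],
                           genome_map: dict[str, str],
                           converged: bool = True) -> FamilySet:
    """Expand subfamily clusters to proteins and genome presence."""
    by_id = {sf.id: sf for sf in subfamilies}
    covered = {sid for cl in clusters for sid in cl}
    all_clusters = list(clusters) + [frozenset([sf.id]) for sf in subfamilies
                                     if sf.id not in covered]
    prot_fam = {}
    rows = []
    genomes = sorted(set(genome_map.values()))
    for fi, cl in enumerate(all_clusters):
        present = set()
        for sid in sorted(cl):
            for p in by_id[sid].members:
                prot_fam[p] = fi
                present.add(genome_map[p])
        rows.append([g in present for g in genomes])
    presence = pd.DataFrame(rows, columns=genomes)
    return FamilySet(families=all_clusters,
                     protein_family=pd.Series(prot_fam),
                     presence=presence, converged=converged,
                     subfamilies=subfamilies)


def core_families(families: FamilySet, genome_map: dict[str, str] | None = None,
                  slack: float = 0.0) -> list[int]:
    """Family indices present in >= (1 - slack) of the genomes."""
    n_genomes = families.presence.shape[1]
    need = (1.0 - slack) * n_genomes
    frac = families.presence.sum(axis=1)
    return [int(i) for i in families.presence.index if frac[i] >= need - 1e-9]


def build_families(proteins: dict[str, str], genome_map: dict[str, str],
                   hits: pd.DataFrame | None = None,
                   evalue_max: float = 1e-3, min_cover: float = 0.5,
                   prob_min: float = 0.95, cover_min: float = 0.5,
                   inflation: float = 2.0, seed: int = 0) -> FamilySet:
    """Full pipeline: network -> subfamilies -> profile graph -> MCL."""
    missing = set(proteins) - set(genome_map)
    if missing:
        raise ValueError(f"proteins without genome mapping: {sorted(missing)[:5]}")
    net = build_network(proteins, hits, evalue_max, min_cover)
    subfams = greedy_set_cover(net)
    for sf in subfams:
        align_members(sf, proteins)
    pg = compare_subfamilies(subfams, prob_min, cover_min, seed=seed)
    clusters, converged = mcl(pg, inflation=inflation)
    return families_from_clusters(clusters, subfams, genome_map, converged)
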