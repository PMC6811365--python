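"""Codon-usage profiles and codon-bias host prediction.

Phage rely on the host translation machinery, so a phage genome's synonymous
codon choices tend to drift toward the codon preferences of its host. This
module computes per-genome codon usage as *synonymous fractions* (for each
amino-acid class, including the stop class, the fraction each codon
contributes within its class; translation table 11), clusters genomes by
Euclidean distance on the 64-long fraction vector with average-linkage
(UPGMA) hierarchical clustering, and reads host candidates for each phage
off the flat clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "CODONS",
    "SYNONYMOUS_CLASSES",
    "CodonUsageProfile",
    "UsageClustering",
    "codon_counts",
    "usage_frequency",
    "profile_from_cds",
    "cluster_profiles",
    "predict_hosts",
]

#: the 64 codons in a fixed lexicographic (A<C<G<T) order
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def _build_classes() -> dict[str, tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    classes: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = "*" if codon in table.stop_codons else table.forward_table[codon]
        classes.setdefault(aa, []).append(codon)
    return {aa: tuple(cs) for aa, cs in classes.items()}


#: amino acid (one-letter, '*' = stop) -> synonymous codons, table 11
SYNONYMOUS_CLASSES: dict[str, tuple[str, ...]] = _build_classes()

#: codon -> its amino-acid class
CODON_TO_CLASS: dict[str, str] = {
    c: aa for aa, cs in SYNONYMOUS_CLASSES.items() for c in cs
}


@dataclass
class CodonCountResult:
    counts: pd.Series  # indexed by the 64 codons
    n_codons: int
    n_ambiguous_skipped: int
    skipped_records: list[tuple[int, str]] = field(default_factory=list)


def codon_counts(cds_set: list[str]) -> CodonCountResult:
    """Exact frame-0 codon tally over a set of CDS.

    Codons containing non-ACGT characters are skipped (counted). CDS whose
    length is not divisible by 3 are skipped entirely and reported in
    ``skipped_records``. An empty CDS set is an error.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts = np.zeros(64, dtype=np.int64)
    n_ambig = 0
    skipped: list[tuple[int, str]] = []
    for i, cds in enumerate(cds_set):
        s = cds.upper()
        if len(s) % 3 != 0:
            skipped.append((i, f"length {len(s)} not divisible by 3"))
            logger.warning("CDS %d skipped: length %d not divisible by 3", i, len(s))
            continue
        arr = np.frombuffer(s.encode(), dtype=np.uint8).reshape(-1, 3)
        code = np.full(256, -1, dtype=np.int16)
        for b, v in zip(b"ACGT", range(4)):
            code[b] = v
        vals = code[arr]
        ok = (vals >= 0).all(axis=1)
        n_ambig += int((~ok).sum())
        idx = vals[ok] @ np.array([16, 4, 1])
        counts += np.bincount(idx, minlength=64)
    return CodonCountResult(
        counts=pd.Series(counts, index=list(CODONS)),
        n_codons=int(counts.sum()),
        n_ambiguous_skipped=n_ambig,
        skipped_records=skipped,
    )


@dataclass
class CodonUsageProfile:
    """Per-genome synonymous-fraction vector over the 64 codons.

    ``counts`` (raw codon tallies) are kept when the profile was built from
    CDS, so the per-1000 companion table can be emitted alongside.
    """

    genome_id: str
    fractions: pd.Series  # indexed by CODONS; per-class fractions
    n_codons: int
    counts: pd.Series | None = None

    def vector(self) -> np.ndarray:
        return self.fractions.to_numpy(dtype=float)

    def per_thousand(self) -> pd.Series:
        """Codon usage per 1000 codons (cusp-style companion output)."""
        if self.counts is None:
            raise ValueError("profile was built without raw counts")
        return self.counts * 1000.0 / self.n_codons


def usage_frequency(counts: CodonCountResult | pd.Series,
                    genome_id: str = "genome") -> CodonUsageProfile:
    """Synonymous fractions: count(codon) / total count of its class.

    Classes absent from the input get all-zero fractions.
    """
    if isinstance(counts, CodonCountResult):
        series = counts.counts
    else:
        series = counts.reindex(list(CODONS)).fillna(0)
    total = int(series.sum())
    if total == 0:
        raise ValueError("no codons counted")
    frac = pd.Series(0.0, index=list(CODONS))
    for aa, codons in SYNONYMOUS_CLASSES.items():
        class_total = series[list(codons)].sum()
        if class_total > 0:
            frac[list(codons)] = series[list(codons)] / class_total
    return CodonUsageProfile(
        genome_id=genome_id, fractions=frac, n_codons=total, counts=series
    )


def profile_from_cds(cds_set: list[str], genome_id: str) -> CodonUsageProfile:
    return usage_frequency(codon_counts(cds_set), genome_id)


def cds_from_genome(seq_or_record, features,
                    exclude_region: tuple[int, int] | None = None) -> list[str]:
    """Extract CDS sequences (strand-aware) from a genome and features.

    ``exclude_region`` drops CDS overlapping a half-open interval — used to
    remove a prophage region before profiling its host.
    """
    seq = getattr(seq_or_record, "seq", seq_or_record)
    out = []
    for f in features:
        if f.type != "CDS":
            continue
        if exclude_region is not None:
            lo, hi = exclude_region
            if f.start < hi and f.end > lo:
                continue
        sub = seq[f.start: f.end]
        if f.strand < 0:
            from .records import revcomp

            sub = revcomp(sub)
        out.append(sub)
    return out


@dataclass
class UsageClustering:
    """UPGMA clustering of codon-usage profiles.

    ``ids`` are sorted lexicographically before clustering so the result is
    independent of input order; ``linkage`` is a scipy linkage matrix over
    Euclidean distances of the 64-vectors.
    """

    ids: list[str]
    distances: pd.DataFrame  # square, symmetric
    linkage: np.ndarray

    def flat_clusters(self, k: int | None = None,
                      height: float | None = None) -> pd.Series:
        """Flat cluster labels at a fixed count ``k`` or cut ``height``.

        With neither given, the cut maximizing the mean silhouette over
        k = 2 .. n-1 is used (the dendrogram-reading step made explicit).
        """
        n = len(self.ids)
        if k is not None:
            labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        elif height is not None:
            labels = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        else:
            best, best_score = None, -np.inf
            dm = self.distances.to_numpy()
            for kk in range(2, n):
                lab = hierarchy.fcluster(self.linkage, t=kk, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                score = silhouette_score(dm, lab, metric="precomputed")
                if score > best_score:
                    best, best_score = lab, score
            labels = best if best is not None else np.ones(n, dtype=int)
        return pd.Series(labels, index=self.ids, name="cluster")

    def to_newick(self) -> str:
        """Export the dendrogram as a Newick string."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return str(tree).strip()


def cluster_profiles(profiles: list[CodonUsageProfile], method: str = "average",
                     metric: str = "euclidean") -> UsageClustering:
    """UPGMA (``average``) dendrogram on pairwise profile distances."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids")
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    mat = np.vstack([profiles[i].vector() for i in order])
    cond = pdist(mat, metric=metric)
    link = hierarchy.linkage(cond, method=method)
    dist = pd.DataFrame(squareform(cond), index=ids_sorted, columns=ids_sorted)
    return UsageClustering(ids=ids_sorted, distances=dist, linkage=link)


def predict_hosts(clustering: UsageClustering, phage_ids: list[str],
                  k: int | None = None,
                  height: float | None = None) -> dict[str, list[str]]:
    """Host candidates: non-phage genomes sharing each phage's flat cluster.

    An empty candidate set (phage-only cluster) is returned as an empty list
    and logged as flagged.
    """
    missing = set(phage_ids) - set(clustering.ids)
    if missing:
        raise ValueError(f"phage ids not in clustering: {sorted(missing)}")
    labels = clustering.flat_clusters(k=k, height=height)
    phage_set = set(phage_ids)
    out: dict[str, list[str]] = {}
    for pid in phage_ids:
        lab = labels[pid]
        cands = [g for g in clustering.ids
                 if labels[g] == lab and g not in phage_set]
        if not cands:
            logger.warning("phage %s falls in a phage-only cluster", pid)
        out[pid] = cands
    return out
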