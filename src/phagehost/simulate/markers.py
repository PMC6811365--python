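"""Synthetic multi-sample marker-gene datasets.

Emulates a metagenome series profiled with single-copy markers: a target
taxon (several rpS3 genotypes), decoy taxa, and phage (TerL genotypes)
whose presence can be coupled to the target ("phage implies host"
co-occurrence). Coverages are lognormal around a per-genotype mean; an
optional planted target fraction fixes the truth relative abundance per
sample. Ground truth (presence, coverages, abundances) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SyntheticTruth
from .proteome import mutate_protein, random_protein

__all__ = [
    "GenotypeSpec",
    "make_genotype_pool",
    "generate_marker_dataset",
    "sample_marker_alignments",
]


@dataclass(frozen=True)
class GenotypeSpec:
    genotype_id: str
    taxon: str
    role: str  # "target" | "other" | "phage"
    marker: str  # "rpS3" | "TerL"
    protein: str


def make_genotype_pool(n_target: int = 4, n_other: int = 3, n_phage: int = 3,
                       seed: int | np.random.Generator = 0,
                       protein_length: int = 220,
                       within_taxon_divergence: float = 0.03,
                       ) -> list[GenotypeSpec]:
    """Genotype pool: target-taxon rpS3 variants, decoy taxa, phage TerL.

    Genotypes of one taxon differ by ``within_taxon_divergence`` of
    positions (default 3%, i.e. distinct at the 99% genotype threshold but
    clearly the same taxon).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_subs = max(1, int(round(within_taxon_divergence * protein_length)))
    pool: list[GenotypeSpec] = []
    target_anc = random_protein(protein_length, rng)
    for i in range(n_target):
        prot = target_anc if i == 0 else mutate_protein(target_anc, n_subs, rng)
        pool.append(GenotypeSpec(f"target_g{i}", "target_taxon", "target",
                                 "rpS3", prot))
    for t in range(n_other):
        anc = random_protein(protein_length, rng)
        pool.append(GenotypeSpec(f"other{t}_g0", f"other_taxon_{t}", "other",
                                 "rpS3", anc))
    phage_anc = random_protein(protein_length, rng)
    for i in range(n_phage):
        prot = phage_anc if i == 0 else mutate_protein(phage_anc, n_subs, rng)
        pool.append(GenotypeSpec(f"phage_g{i}", "phage", "phage", "TerL", prot))
    return pool


def generate_marker_dataset(n_samples: int, genotype_pool: list[GenotypeSpec],
                            presence_model: str = "phage_implies_host",
                            seed: int | np.random.Generator = 0,
                            presence_prob: float = 0.45,
                            mean_coverage: float = 10.0,
                            lognorm_sigma: float = 0.5,
                            target_fraction: float | None = None,
                            ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-sample marker occurrences and coverages with recorded truth.

    Returns a long-form table (sample, genotype_id, taxon, role, marker,
    protein, coverage) of detected markers, plus truth. With
    ``presence_model="phage_implies_host"`` every phage-positive sample is
    guaranteed at least one target genotype. ``target_fraction`` rescales
    target coverages so the planted per-sample relative abundance
    a/b = target/(all bacterial) is exact.
    """
    if not genotype_pool:
        raise ValueError("genotype_pool must be non-empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = [g.genotype_id for g in genotype_pool]
    roles = {g.genotype_id: g.role for g in genotype_pool}
    samples = [f"sample_{i:03d}" for i in range(n_samples)]
    pres = pd.DataFrame(
        rng.random((len(ids), n_samples)) < presence_prob,
        index=ids, columns=samples,
    )
    target_ids = [g for g in ids if roles[g] == "target"]
    other_ids = [g for g in ids if roles[g] == "other"]
    phage_ids = [g for g in ids if roles[g] == "phage"]
    for s in samples:
        if presence_model == "phage_implies_host":
            if pres.loc[phage_ids, s].any() and not pres.loc[target_ids, s].any():
                pick = target_ids[rng.integers(0, len(target_ids))]
                pres.loc[pick, s] = True
        if target_fraction is not None:
            # abundance planting needs both sides of the ratio present
            if not pres.loc[target_ids, s].any():
                pres.loc[target_ids[rng.integers(0, len(target_ids))], s] = True
            if other_ids and not pres.loc[other_ids, s].any():
                pres.loc[other_ids[rng.integers(0, len(other_ids))], s] = True

    mu = np.log(mean_coverage) - lognorm_sigma ** 2 / 2
    cov = np.where(
        pres.to_numpy(),
        rng.lognormal(mu, lognorm_sigma, size=pres.shape), 0.0,
    )
    cov = pd.DataFrame(cov, index=ids, columns=samples)
    if target_fraction is not None:
        f = target_fraction
        for s in samples:
            t = cov.loc[target_ids, s].sum()
            o = cov.loc[other_ids, s].sum()
            if t > 0 and o > 0:
                cov.loc[target_ids, s] *= (f / (1 - f)) * o / t

    rows = []
    proteins = {g.genotype_id: g for g in genotype_pool}
    for s in samples:
        for gid in ids:
            if pres.loc[gid, s]:
                g = proteins[gid]
                rows.append((s, gid, g.taxon, g.role, g.marker, g.protein,
                             float(cov.loc[gid, s])))
    table = pd.DataFrame(rows, columns=["sample", "genotype_id", "taxon",
                                        "role", "marker", "protein",
                                        "coverage"])
    b = cov.loc[target_ids + other_ids].sum(axis=0)
    a = cov.loc[target_ids].sum(axis=0)
    c = cov.loc[phage_ids].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abund = pd.DataFrame({
            "a": a, "b": b, "c": c,
            "taxon_pct": np.where(b > 0, a / b * 100.0, np.nan),
            "phage_pct": np.where(b > 0, c / b * 100.0, np.nan),
        })
    truth = SyntheticTruth(presence=pres, coverages=cov, abundances=abund)
    return table, truth


def sample_marker_alignments(coverages: pd.Series, gene_lengths: pd.Series,
                             read_length: int = 150,
                             error_rate: float = 0.001,
                             rng: np.random.Generator | None = None,
                             ) -> pd.DataFrame:
    """Poisson read sampling from per-gene coverages for one sample.

    Emits one alignment row per read (``read_id, ref, mate, pos, strand,
    nm, m_len``): counts are Poisson with mean coverage x length /
    read_length, so the coverage re-estimated from the table fluctuates
    with read-sampling noise around the planted value.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    rid = 0
    for gene, cov in coverages.items():
        L = int(gene_lengths[gene])
        lam = cov * L / read_length
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            continue
        nm = rng.binomial(read_length, error_rate, size=n)
        pos = rng.integers(0, max(1, L - read_length + 1), size=n)
        for k in range(n):
            rows.append((rid, gene, 1, int(pos[k]), 1, int(nm[k]), read_length))
            rid += 1
    return pd.DataFrame(rows, columns=["read_id", "ref", "mate", "pos",
                                       "strand", "nm", "m_len"])
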