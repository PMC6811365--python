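"""Marker-gene genotype clustering, occurrence and relative abundance.

Single-copy markers (bacterial rpS3, phage TerL) are clustered into
*genotypes* at an amino-acid identity threshold (>= 99% for genotype
resolution, 100% for dereplication, 80% for coarse TerL grouping);
genotype-by-sample occurrence supports host-phage co-occurrence analysis,
and per-gene read coverages (mismatch-filtered) yield accumulated relative
abundances: for a sample, a = summed coverage of target-taxon markers,
b = summed coverage of all bacterial/archaeal markers, c = summed phage
marker coverage, with relative abundances a/b x 100% and c/b x 100%.

Identity here is always global-alignment identity (identical columns over
alignment columns, gaps in the denominator; BLOSUM62, gap open 11 /
extend 1) — one explicit definition used everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dp import global_identity

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSeq",
    "GenotypeTable",
    "AbundanceResult",
    "pairwise_identity",
    "cluster_genotypes",
    "occurrence_matrix",
    "coverage_from_alignments",
    "relative_abundance",
    "filter_alignment_columns",
]


@dataclass(frozen=True)
class MarkerSeq:
    """One marker observation: a protein from one sample with a coverage."""

    id: str
    sample_id: str
    marker: str  # "rpS3" | "TerL" | other
    protein: str
    nucleotide: str | None = None
    coverage: float = 0.0

    def __post_init__(self):
        if not self.protein:
            raise ValueError("protein sequence must be non-empty")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Global-alignment amino-acid identity (gaps count in the denominator)."""
    ident, _ = global_identity(seq1, seq2)
    return ident


@dataclass
class GenotypeTable:
    """Greedy identity clustering of marker sequences.

    ``members`` maps genotype representative id -> list of MarkerSeq; every
    member has identity >= threshold to its representative.
    """

    threshold: float
    members: dict[str, list[MarkerSeq]] = field(default_factory=dict)
    representatives: dict[str, MarkerSeq] = field(default_factory=dict)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.members)


def cluster_genotypes(markers: list[MarkerSeq], threshold: float,
                      ) -> GenotypeTable:
    """Greedy incremental clustering (cd-hit-style order).

    Sequences are sorted by length descending then id; each joins the
    first existing representative with identity >= threshold, else founds
    a new genotype. Threshold 1.0 reduces to exact-string dereplication.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    table = GenotypeTable(threshold=threshold)
    order = sorted(markers, key=lambda m: (-len(m.protein), m.id))
    for m in order:
        placed = False
        for rep_id, rep in table.representatives.items():
            if threshold == 1.0:
                ident = 1.0 if m.protein == rep.protein else 0.0
            elif m.protein == rep.protein:
                ident = 1.0
            else:
                ident = pairwise_identity(m.protein, rep.protein)
            if ident >= threshold:
                table.members[rep_id].append(m)
                placed = True
                break
        if not placed:
            table.representatives[m.id] = m
            table.members[m.id] = [m]
    return table


def occurrence_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Genotype x sample member counts (presence = count >= 1)."""
    samples = sorted({m.sample_id for ms in table.members.values() for m in ms})
    out = pd.DataFrame(0, index=list(table.members), columns=samples)
    for gid, ms in table.members.items():
        for m in ms:
            out.loc[gid, m.sample_id] += 1
    return out


def coverage_from_alignments(alignments: pd.DataFrame,
                             gene_lengths: pd.Series | dict,
                             max_mismatch: int = 3) -> pd.Series:
    """Per-gene coverage = summed aligned bases / gene length.

    Alignments need ``ref``, ``nm`` and an aligned length (``m_len``);
    reads with more than ``max_mismatch`` mismatches are dropped. A
    missing mismatch value is an error naming the record.
    """
    gl = pd.Series(gene_lengths, dtype=float)
    if "nm" not in alignments.columns:
        raise ValueError("alignment table lacks the nm (mismatch) column")
    bad = alignments["nm"].isna()
    if bad.any():
        rid = alignments.loc[bad].iloc[0].get("read_id", "<unknown>")
        raise ValueError(f"missing mismatch count for read {rid!r}")
    kept = alignments[alignments["nm"] <= max_mismatch]
    summed = kept.groupby("ref")["m_len"].sum()
    cov = summed.reindex(gl.index).fillna(0.0) / gl
    return cov


@dataclass
class AbundanceResult:
    sample_id: str
    a: float  # target-taxon marker coverage sum
    b: float  # all bacterial/archaeal marker coverage sum
    c: float  # target-phage marker coverage sum
    taxon_pct: float | None
    phage_pct: float | None
    undefined: bool = False


def relative_abundance(coverages: pd.Series | dict, target_ids: list[str],
                       phage_ids: list[str],
                       sample_id: str = "sample") -> AbundanceResult:
    """Accumulated relative abundance a/b x 100% and c/b x 100%.

    ``coverages`` maps marker/gene id -> coverage for one sample. Phage
    markers are excluded from b (they are not bacterial/archaeal markers).
    b = 0 yields an undefined (flagged) result rather than 0%.
    """
    cov = pd.Series(coverages, dtype=float)
    missing = set(target_ids) - set(cov.index)
    if missing:
        raise ValueError(f"target ids absent from coverages: {sorted(missing)}")
    phage_set = set(phage_ids)
    bact = [i for i in cov.index if i not in phage_set]
    a = float(cov[list(target_ids)].sum())
    b = float(cov[bact].sum())
    c = float(cov[[i for i in cov.index if i in phage_set]].sum())
    if b <= 0:
        logger.warning("sample %s: no bacterial marker coverage (b=0)", sample_id)
        return AbundanceResult(sample_id, a, b, c, None, None, undefined=True)
    return AbundanceResult(sample_id, a, b, c, a / b * 100.0, c / b * 100.0)


def filter_alignment_columns(msa: list[str], max_gap_fraction: float = 0.95,
                             trim_termini: bool = True,
                             terminus_gap_fraction: float = 0.5,
                             ) -> tuple[list[str], np.ndarray]:
    """Drop alignment columns with gap fraction strictly above the cutoff.

    Optionally trims ambiguous termini: leading and trailing columns are
    removed up to the first column whose gap fraction is <=
    ``terminus_gap_fraction``. Returns (filtered rows, kept column
    indices). Rows must have equal length; an empty alignment is an error.
    """
    if not msa:
        raise ValueError("empty alignment")
    L = len(msa[0])
    if any(len(r) != L for r in msa):
        raise ValueError("alignment rows differ in length")
    if L == 0:
        raise ValueError("alignment has no columns")
    mat = np.array([list(r) for r in msa])
    gap_frac = ((mat == "-") | (mat == ".")).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if trim_termini:
        solid = np.flatnonzero(gap_frac <= terminus_gap_fraction)
        if len(solid):
            keep[: solid[0]] = False
            keep[solid[-1] + 1:] = False
        else:
            keep[:] = False
    idx = np.flatnonzero(keep)
    return ["".join(row[idx]) for row in mat], idx
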