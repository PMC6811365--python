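"""Prophage resolution from a lysogen scaffold.

A prophage integrated at a tRNA gene is delimited by *attL* and *attR*,
identical direct repeats of a short "core" duplicated on integration. This
module locates candidate att pairs as maximal identical direct repeats at
prophage-like spacing, quantifies paired-read evidence for the excised
circular phage (free particles) and for prophage-free host cells (attB
continuity), excises the prophage (one core copy retained in the cured
host, the phage rotated to begin at the core and marked circular), and
reports the gene at the integration site.

Candidate ranking exploits integration-site biology: a repeat whose copies
end exactly at annotated tRNA 3' ends outranks everything else, because
tRNA-targeting integrases regenerate an intact tRNA at attL while the
prophage carries its own tRNA copy ending at attR. Direct-repeat length
alone cannot single out an ~11-bp core: a 40-kb genome at GC 0.3 contains
hundreds of chance repeats of that length. Without annotations the ranking
falls back to (core length, spacing closest to the expected phage size,
leftmost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Feature, GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AttPair",
    "ReadEvidence",
    "IntegrationReport",
    "ProphageCall",
    "find_att_pairs",
    "score_read_evidence",
    "excise_prophage",
    "insert_at_attB",
    "classify_integration_site",
    "resolve_prophage",
]


@dataclass(frozen=True)
class AttPair:
    """attL/attR as 0-based half-open intervals with their shared core."""

    attL: tuple[int, int]
    attR: tuple[int, int]
    core: str
    trna_matched: int = 0  # how many core copies end at a tRNA 3' end (0-2)
    degenerate: bool = False  # core occurs more than twice in the scaffold

    def __post_init__(self):
        (l0, l1), (r0, r1) = self.attL, self.attR
        if l1 - l0 != len(self.core) or r1 - r0 != len(self.core):
            raise ValueError("att interval lengths must equal the core length")
        if r0 < l1:
            raise ValueError("attL must lie strictly left of attR")

    @property
    def core_length(self) -> int:
        return len(self.core)

    @property
    def spacing(self) -> int:
        """attR start minus attL start == length of the excisable segment."""
        return self.attR[0] - self.attL[0]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers (A=0..T=3); ambiguous bases poison to -1."""
    code = np.full(256, -1, dtype=np.int64)
    for b, v in zip(b"ACGT", range(4)):
        code[b] = v
    vals = code[arr]
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    bad = (win < 0).any(axis=1)
    codes[bad] = -1
    return codes


def _maximal_extension(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Extend a shared k-mer at (i, j) to the maximal identical repeat."""
    left = 0
    while i - left - 1 >= 0 and seq[i - left - 1] == seq[j - left - 1]:
        left += 1
    right = 0
    n = len(seq)
    while j + k + right < n and seq[i + k + right] == seq[j + k + right]:
        right += 1
    return i - left, j - left, k + left + right


def find_att_pairs(lysogen: GenomeRecord | str, min_core: int = 10,
                   max_core: int = 50,
                   region_hint: tuple[int, int] | None = None,
                   spacing_bounds: tuple[int, int] = (10_000, 100_000),
                   expected_size: int = 40_000,
                   annotations: list[Feature] | None = None,
                   max_kmer_multiplicity: int = 64,
                   max_returned: int = 100) -> list[AttPair]:
    """All maximal identical direct repeats at prophage-like spacing, ranked.

    Repeats of length in [min_core, max_core] whose copies are separated by
    a spacing within ``spacing_bounds`` are returned, ranked by
    (tRNA-3'-end match desc, core length desc, |spacing - expected_size|
    asc, leftmost). ``region_hint`` restricts both copies to a window.
    Returns an empty list when nothing qualifies.
    """
    seq = lysogen.seq if isinstance(lysogen, GenomeRecord) else lysogen
    if min_core < 8:
        raise ValueError("min_core must be >= 8")
    lo, hi = region_hint if region_hint else (0, len(seq))
    window = seq[lo:hi]
    if len(window) < min_core:
        return []
    arr = np.frombuffer(window.encode(), dtype=np.uint8)
    codes = _kmer_codes(arr, min_core)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    groups = np.split(order, boundaries)

    smin, smax = spacing_bounds
    seen: set[tuple[int, int, int]] = set()
    candidates: list[tuple[int, int, int]] = []
    for g in groups:
        if len(g) < 2 or codes[g[0]] < 0:
            continue
        if len(g) > max_kmer_multiplicity:
            logger.warning("skipping %d-fold repeated seed k-mer", len(g))
            continue
        pos = np.sort(g)
        for ai in range(len(pos)):
            for bi in range(ai + 1, len(pos)):
                i, j = int(pos[ai]) + lo, int(pos[bi]) + lo
                if not (smin <= j - i <= smax + max_core):
                    continue
                rep = _maximal_extension(seq, i, j, min_core)
                if rep in seen:
                    continue
                seen.add(rep)
                candidates.append(rep)

    trna_ends: set[int] = set()
    if annotations:
        for f in annotations:
            if f.type == "tRNA":
                trna_ends.add(f.end if f.strand >= 0 else f.start + 0)
                if f.strand < 0:
                    trna_ends.add(f.start)

    pairs: list[AttPair] = []
    for i, j, length in candidates:
        if not (min_core <= length <= max_core):
            continue
        if j < i + length:  # overlapping copies
            continue
        if not (smin <= j - i <= smax):
            continue
        core = seq[i: i + length]
        matched = int(i + length in trna_ends) + int(j + length in trna_ends)
        pairs.append(AttPair((i, i + length), (j, j + length), core,
                             trna_matched=matched))
    pairs.sort(key=lambda p: (-p.trna_matched, -p.core_length,
                              abs(p.spacing - expected_size), p.attL[0]))
    pairs = pairs[:max_returned]
    out = []
    for p in pairs[:50]:
        n_occ = seq.count(p.core)
        if n_occ > 2:
            logger.warning("core %r occurs %d times", p.core, n_occ)
            p = AttPair(p.attL, p.attR, p.core, p.trna_matched, True)
        out.append(p)
    return out + pairs[50:]


# ---------------------------------------------------------------------------
# read evidence


@dataclass
class ReadEvidence:
    """Pair-level evidence at an att pair.

    ``circularizing_fraction`` is junction pairs over (junction pairs +
    pairs covering an att locus consistent with the integrated state); it
    is ``None`` (``undefined=True``) when no informative pair exists.
    """

    n_junction_pairs: int
    n_attB_spanning_pairs: int
    n_integrated_pairs: int
    n_internal_pairs: int
    circularizing_fraction: float | None
    undefined: bool = False


def score_read_evidence(lysogen: GenomeRecord | str, att: AttPair,
                        read_pairs: pd.DataFrame,
                        max_mismatch: int = 3,
                        max_span: int = 1_000,
                        margin: int = 50) -> ReadEvidence:
    """Classify aligned read pairs at an att pair.

    ``read_pairs`` uses the numeric alignment columns (``read_id, mate,
    pos, strand, nm, m_len, clip_left, clip_right``); see
    ``simulate.reads.read_alignment_tsv`` for the TSV form. Junction
    evidence is a soft clip landing exactly on the att junction (clip
    beyond attR's core end, or clip onto attL's core start) or an everted
    pair inside the prophage; attB evidence is the mirrored clip signature
    or a pair spanning the whole prophage at deleted-state spacing.
    """
    (s1, e1), (s2, e2) = att.attL, att.attR
    df = read_pairs[read_pairs["nm"] <= max_mismatch]
    # pair up mates
    counts = df.groupby("read_id")["mate"].transform("size")
    df = df[counts == 2]
    fwd = df[df["strand"] > 0].set_index("read_id")
    rev = df[df["strand"] < 0].set_index("read_id")
    common = fwd.index.intersection(rev.index)
    fwd, rev = fwd.loc[common], rev.loc[common]

    def read_flags(part):
        m_end = part["pos"] + part["m_len"]
        junc = ((part["clip_right"] > 0) & (m_end == e2)) | \
               ((part["clip_left"] > 0) & (part["pos"] == s1))
        attb = ((part["clip_right"] > 0) & (m_end == e1)) | \
               ((part["clip_left"] > 0) & (part["pos"] == s2))
        return junc, attb

    jf, af = read_flags(fwd)
    jr, ar = read_flags(rev)
    junction_clip = (jf | jr).to_numpy()
    attb_clip = (af | ar).to_numpy()

    fwd_pos = fwd["pos"].to_numpy()
    fwd_end = (fwd["pos"] + fwd["m_len"]).to_numpy()
    rev_pos = rev["pos"].to_numpy()
    rev_end = (rev["pos"] + rev["m_len"]).to_numpy()
    full = ((fwd["clip_left"] + fwd["clip_right"] == 0).to_numpy() &
            (rev["clip_left"] + rev["clip_right"] == 0).to_numpy())

    in_region = ((fwd_pos >= s1 - margin) & (fwd_end <= e2 + margin) &
                 (rev_pos >= s1 - margin) & (rev_end <= e2 + margin))
    everted = in_region & (fwd_pos > rev_pos)
    junction = junction_clip | everted

    span = np.maximum(fwd_end, rev_end) - np.minimum(fwd_pos, rev_pos)
    attb_span = (~junction) & (fwd_pos < s1) & (rev_end > e2) & (span > max_span)
    attb = (~junction) & (attb_clip | attb_span)

    normal = full & (fwd_pos <= rev_pos) & (span <= max_span)
    covers = (((fwd_pos <= s1 - 1) & (rev_end >= e1 + 1)) |
              ((fwd_pos <= s2 - 1) & (rev_end >= e2 + 1)))
    integrated = (~junction) & (~attb) & normal & covers

    touches = (np.minimum(fwd_pos, rev_pos) <= e2 + margin) & \
              (np.maximum(fwd_end, rev_end) >= s1 - margin)
    internal = touches & ~(junction | attb | integrated)

    nj = int(junction.sum())
    na = int(attb.sum())
    ni = int(integrated.sum())
    denom = nj + ni
    frac = (nj / denom) if denom else None
    if denom == 0:
        logger.warning("no informative pairs at %s; fraction undefined", att)
    return ReadEvidence(
        n_junction_pairs=nj, n_attB_spanning_pairs=na,
        n_integrated_pairs=ni, n_internal_pairs=int(internal.sum()),
        circularizing_fraction=frac, undefined=denom == 0,
    )


# ---------------------------------------------------------------------------
# excision


def excise_prophage(lysogen: GenomeRecord, att: AttPair,
                    ) -> tuple[GenomeRecord, GenomeRecord]:
    """Remove [attL_start, attR_start), keeping one core copy (attB).

    Returns the cured host and the circular phage rotated to begin at the
    core; lengths conserve: len(lysogen) == len(cured) + len(phage).
    """
    (s1, e1), (s2, e2) = att.attL, att.attR
    if e1 > s2:
        raise ValueError("overlapping att intervals")
    seq = lysogen.seq
    if seq[s1:e1] != att.core or seq[s2:e2] != att.core:
        raise ValueError("att intervals do not match the core on the scaffold")
    cured = GenomeRecord(id=lysogen.id + "_cured", seq=seq[:s1] + seq[s2:],
                         circular=lysogen.circular)
    phage = GenomeRecord(id=lysogen.id + "_phage", seq=seq[s1:s2],
                         circular=True)
    assert len(lysogen.seq) == len(cured.seq) + len(phage.seq)
    return cured, phage


def insert_at_attB(cured: GenomeRecord, phage: GenomeRecord,
                   attB_start: int) -> GenomeRecord:
    """Inverse of excision: re-integrate a core-rotated circular phage."""
    core_len = None
    seq = phage.seq
    # the phage begins with the core; attB carries the same core
    for c in range(min(len(seq), 60), 0, -1):
        if cured.seq[attB_start: attB_start + c] == seq[:c]:
            core_len = c
            break
    if core_len is None:
        raise ValueError("phage start does not match attB")
    return GenomeRecord(
        id=cured.id + "_relysogen",
        seq=cured.seq[:attB_start] + seq + cured.seq[attB_start:],
        circular=cured.circular,
    )


# ---------------------------------------------------------------------------
# integration-site classification


@dataclass
class IntegrationReport:
    integration_gene: Feature | None
    anticodon: str | None
    left_flank: Feature | None
    right_flank: Feature | None


def classify_integration_site(att: AttPair,
                              annotations: list[Feature]) -> IntegrationReport:
    """Report the gene overlapping the att cores and the flanking genes."""
    (s1, e1), (s2, e2) = att.attL, att.attR
    hit = None
    for f in annotations:
        if (f.start < e1 and f.end > s1) or (f.start < e2 and f.end > s2):
            if hit is None or (f.type == "tRNA" and hit.type != "tRNA"):
                hit = f
    anticodon = hit.attributes.get("anticodon") if hit is not None else None
    left = None
    for f in annotations:
        if f.end <= s1 and (left is None or f.end > left.end):
            left = f
    right = None
    for f in annotations:
        if f.start >= e2 and (right is None or f.start < right.start):
            right = f
    return IntegrationReport(hit, anticodon, left, right)


# ---------------------------------------------------------------------------
# one-call resolution


@dataclass
class ProphageCall:
    att: AttPair
    phage: GenomeRecord
    cured_host: GenomeRecord
    evidence: ReadEvidence | None
    integration: IntegrationReport | None
    alternatives: list[AttPair] = field(default_factory=list)


def resolve_prophage(lysogen: GenomeRecord,
                     annotations: list[Feature] | None = None,
                     read_pairs: pd.DataFrame | None = None,
                     **find_kwargs) -> ProphageCall | None:
    """Find the best att pair, excise, and collect evidence in one call."""
    pairs = find_att_pairs(lysogen, annotations=annotations, **find_kwargs)
    if not pairs:
        return None
    best = pairs[0]
    cured, phage = excise_prophage(lysogen, best)
    evidence = (score_read_evidence(lysogen, best, read_pairs)
                if read_pairs is not None else None)
    integration = (classify_integration_site(best, annotations)
                   if annotations is not None else None)
    return ProphageCall(att=best, phage=phage, cured_host=cured,
                        evidence=evidence, integration=integration,
                        alternatives=pairs[1:10])
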