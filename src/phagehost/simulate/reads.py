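"""Paired-end read simulation with truth-projected alignment summaries.

Fragments are drawn from community members proportional to weight x
length, with normally distributed insert sizes, inward-facing mates and a
flat per-base substitution error rate. Besides (optional) read sequences,
the simulator emits an *idealized alignment table* against a chosen
reference: each member carries a block map describing how its coordinates
project onto the reference, and reads crossing a block breakpoint (the
circular-phage junction, or the attB junction of a prophage-free cell) are
reported the way a mapper would place them — the longer segment aligned,
extended through the duplicated att core, the remainder soft-clipped.

The alignment table uses the columns ``read_id, mate, ref, pos0, strand,
nm, cigar`` plus pre-parsed numeric clip columns, and is the tabular
"per-read alignment summary" input consumed by the prophage resolver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..records import GenomeRecord, revcomp
from .config import SimConfig

__all__ = [
    "MemberSpec",
    "ReadPool",
    "simulate_reads",
    "reads_to_fastq",
    "write_alignment_tsv",
    "read_alignment_tsv",
    "naive_map_reads",
    "expected_fragment_length",
    "weights_for_circularizing_fraction",
    "pairs_for_informative_count",
]


@dataclass
class MemberSpec:
    """A community member and its projection onto the reference.

    ``blocks`` is a list of ``(member_start, member_end, ref_start)`` with
    non-decreasing member coordinates; ``dup`` is the length of the
    sequence duplicated across breakpoints (the att core), through which
    alignments extend before soft-clipping.
    """

    record: GenomeRecord
    weight: float
    circular: bool = False
    blocks: list[tuple[int, int, int]] | None = None
    dup: int = 0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("member weight must be positive")
        if self.blocks is None:
            self.blocks = [(0, len(self.record.seq), 0)]


@dataclass
class ReadPool:
    """Simulated pairs: one row per mate in ``alignments``."""

    alignments: pd.DataFrame
    members: list[MemberSpec]
    cfg: SimConfig
    sequences: pd.DataFrame | None = None  # read_id, mate, seq (if materialized)
    ref_id: str = "reference"


def expected_fragment_length(cfg: SimConfig) -> float:
    """E[fragment length] after clipping at [2 * read_length, inf)."""
    mu, sd, lo = cfg.insert_mean, cfg.insert_sd, 2 * cfg.read_length
    if sd == 0:
        return float(max(mu, lo))
    a = (lo - mu) / sd
    return float(lo * norm.cdf(a) + mu * (1 - norm.cdf(a)) + sd * norm.pdf(a))


def _segments_for_interval(a: np.ndarray, length: int, circular: bool,
                           starts: np.ndarray, ends: np.ndarray,
                           refs: np.ndarray, R: int):
    """Map member read intervals [a, a+R) to up to two reference segments."""
    n = len(a)
    a = a % length if circular else a
    b = a + R
    # wrap split (circular members)
    wrap = circular & (b > length)
    len1 = np.where(wrap, length - a, R)
    # block split: block of position a
    bi = np.searchsorted(starts, a, side="right") - 1
    block_end = ends[bi]
    crosses = (a + len1) > block_end
    len1 = np.where(crosses, block_end - a, len1)
    len2 = R - len1
    rs1 = refs[bi] + (a - starts[bi])
    # the second segment starts at member coord (a + len1) mod length
    a2 = (a + len1) % length
    bi2 = np.searchsorted(starts, a2, side="right") - 1
    rs2 = refs[bi2] + (a2 - starts[bi2])
    return rs1.astype(np.int64), len1.astype(np.int64), rs2.astype(np.int64), len2.astype(np.int64)


def _project_member(member: MemberSpec, f0: np.ndarray, Lf: np.ndarray,
                    R: int) -> dict[str, np.ndarray]:
    """Project both mates of each fragment; returns per-mate arrays."""
    blocks = np.array(member.blocks, dtype=np.int64)
    starts, ends, refs = blocks[:, 0], blocks[:, 1], blocks[:, 2]
    length = len(member.record.seq)
    out = {}
    for mate, (a, strand) in enumerate(
        [(f0, 1), (f0 + Lf - R, -1)], start=1
    ):
        rs1, len1, rs2, len2 = _segments_for_interval(
            a, length, member.circular, starts, ends, refs, R
        )
        ext = np.minimum(member.dup, len2)
        prefix_primary = (len1 + ext) >= len2
        pos = np.where(prefix_primary, rs1, rs2)
        m_len = np.where(prefix_primary, len1 + ext, len2)
        clip_left = np.where(prefix_primary, 0, len1)
        clip_right = np.where(prefix_primary, len2 - ext, 0)
        out[mate] = dict(pos=pos, m_len=m_len, clip_left=clip_left,
                         clip_right=clip_right, strand=np.full(len(a), strand),
                         read_start=a)
    return out


def simulate_reads(members: list[MemberSpec], cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   with_sequences: bool = False,
                   ref_id: str = "reference") -> ReadPool:
    """Draw ``cfg.n_pairs`` pairs from the community.

    Pairs are allocated to members proportional to weight x length;
    fragment lengths are normal (clipped to at least two read lengths) and
    mates face inward. Deterministic for a fixed rng state.
    """
    if rng is None:
        rng = cfg.rng("reads")
    R = cfg.read_length
    if cfg.insert_mean < R:
        raise ValueError("insert_mean must be >= read_length")
    w = np.array([m.weight * len(m.record.seq) for m in members], dtype=float)
    alloc = rng.multinomial(cfg.n_pairs, w / w.sum())
    frames = []
    seq_rows = []
    next_id = 0
    for mi, (member, n_m) in enumerate(zip(members, alloc)):
        if n_m == 0:
            continue
        L = len(member.record.seq)
        Lf = np.clip(np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, n_m)),
                     2 * R, L).astype(np.int64)
        if member.circular:
            f0 = rng.integers(0, L, size=n_m)
        else:
            f0 = rng.integers(0, L - Lf + 1)
        proj = _project_member(member, f0, Lf, R)
        ids = np.arange(next_id, next_id + n_m)
        next_id += n_m
        err = rng.binomial(R, cfg.error_rate, size=(n_m, 2))
        for mate in (1, 2):
            p = proj[mate]
            if with_sequences:
                nm_m, seqs = _materialize(member, p, mate, R,
                                          err[:, mate - 1], rng, ids)
                seq_rows.extend(seqs)
            else:
                full = p["m_len"] == R
                nm_m = np.where(
                    full, err[:, mate - 1],
                    rng.hypergeometric(p["m_len"], R - p["m_len"],
                                       err[:, mate - 1]),
                )
            frames.append(pd.DataFrame({
                "read_id": ids, "mate": mate, "ref": ref_id,
                "pos": p["pos"], "strand": p["strand"], "nm": nm_m,
                "m_len": p["m_len"], "clip_left": p["clip_left"],
                "clip_right": p["clip_right"], "member": mi,
                "frag_start": f0, "frag_len": Lf,
            }))
    aln = pd.concat(frames, ignore_index=True).sort_values(
        ["read_id", "mate"], kind="stable").reset_index(drop=True)
    sequences = (pd.DataFrame(seq_rows, columns=["read_id", "mate", "seq"])
                 if with_sequences else None)
    return ReadPool(alignments=aln, members=members, cfg=cfg,
                    sequences=sequences, ref_id=ref_id)


def _materialize(member: MemberSpec, p: dict, mate: int, R: int,
                 n_err: np.ndarray, rng: np.random.Generator,
                 ids: np.ndarray):
    """Extract read sequences, apply errors, count nm inside the M part."""
    seq = member.record.seq
    ext = seq + seq[:2 * R] if member.circular else seq
    rows = []
    nm_m = np.zeros(len(ids), dtype=np.int64)
    for j in range(len(ids)):
        a = int(p["read_start"][j]) % len(seq)
        s = ext[a: a + R]
        k = int(n_err[j])
        err_pos = (rng.choice(R, size=k, replace=False) if k else
                   np.empty(0, dtype=int))
        if k:
            sl = list(s)
            for pos in err_pos:
                alt = [b for b in "ACGT" if b != sl[pos]]
                sl[pos] = alt[rng.integers(0, 3)]
            s = "".join(sl)
        # nm within the aligned part: read offsets [clip_left, clip_left+m_len)
        cl = int(p["clip_left"][j])
        ml = int(p["m_len"][j])
        nm_m[j] = int(((err_pos >= cl) & (err_pos < cl + ml)).sum())
        if mate == 2:
            s = revcomp(s)
        rows.append((int(ids[j]), mate, s))
    return nm_m, rows


def reads_to_fastq(pool: ReadPool, path_r1, path_r2) -> None:
    """Write materialized pairs as two Phred+33 FASTQ files (flat Q30)."""
    if pool.sequences is None:
        raise ValueError("pool was simulated without sequences "
                         "(use with_sequences=True)")
    qual = "?"  # Q30; the simulator has no quality model
    handles = {1: open(path_r1, "w"), 2: open(path_r2, "w")}
    try:
        for row in pool.sequences.itertuples():
            handles[row.mate].write(
                f"@read_{row.read_id}/{row.mate}\n{row.seq}\n+\n"
                f"{qual * len(row.seq)}\n"
            )
    finally:
        for fh in handles.values():
            fh.close()


# ---------------------------------------------------------------------------
# serialization


def _cigar(row) -> str:
    parts = []
    if row.clip_left:
        parts.append(f"{row.clip_left}S")
    parts.append(f"{row.m_len}M")
    if row.clip_right:
        parts.append(f"{row.clip_right}S")
    return "".join(parts)


def write_alignment_tsv(pool_or_df, path) -> None:
    """Write the simplified alignment table (spec columns + cigar)."""
    df = pool_or_df.alignments if isinstance(pool_or_df, ReadPool) else pool_or_df
    out = pd.DataFrame({
        "read_id": df["read_id"], "mate": df["mate"], "ref": df["ref"],
        "pos0": df["pos"],
        "strand": np.where(df["strand"] > 0, "+", "-"),
        "nm": df["nm"],
        "cigar": [_cigar(r) for r in df.itertuples()],
    })
    out.to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path) -> pd.DataFrame:
    """Parse the simplified table back into numeric alignment columns."""
    import re

    df = pd.read_csv(path, sep="\t")
    pat = re.compile(r"^(?:(\d+)S)?(\d+)M(?:(\d+)S)?$")
    cl, ml, cr = [], [], []
    for c in df["cigar"].astype(str):
        m = pat.match(c)
        if not m:
            raise ValueError(f"unsupported cigar {c!r} (xS yM zS expected)")
        cl.append(int(m.group(1) or 0))
        ml.append(int(m.group(2)))
        cr.append(int(m.group(3) or 0))
    return pd.DataFrame({
        "read_id": df["read_id"], "mate": df["mate"], "ref": df["ref"],
        "pos": df["pos0"],
        "strand": np.where(df["strand"].astype(str) == "+", 1, -1),
        "nm": df["nm"], "m_len": ml, "clip_left": cl, "clip_right": cr,
    })


def naive_map_reads(reads: list[tuple[str, str]], reference: str,
                    max_hits: int = 2) -> pd.DataFrame:
    """Exact-substring mapper for small error-free synthetic tests."""
    rows = []
    for rid, seq in reads:
        for strand, s in ((1, seq), (-1, revcomp(seq))):
            start = reference.find(s)
            while start >= 0 and max_hits:
                rows.append((rid, start, strand, 0, len(s)))
                start = reference.find(s, start + 1)
        # unmapped reads are simply absent from the table
    return pd.DataFrame(rows, columns=["read_id", "pos", "strand", "nm", "m_len"])


# ---------------------------------------------------------------------------
# planting helpers: expected informative-pair geometry


def _p_junction(cfg: SimConfig, phage_len: int, core_len: int) -> float:
    return (expected_fragment_length(cfg) - 1 - core_len) / phage_len


def _p_integrated(cfg: SimConfig, lysogen_len: int, core_len: int) -> float:
    e = expected_fragment_length(cfg)
    return 2.0 * (e - core_len - 1) / (lysogen_len - e + 1)


def weights_for_circularizing_fraction(target: float, lysogen_len: int,
                                       phage_len: int, core_len: int,
                                       cfg: SimConfig,
                                       lysogen_weight: float = 1.0) -> float:
    """Free-phage weight planting an expected circularizing fraction.

    Solves target = J / (J + D) where J and D are the expected
    junction-pair and integrated-att-covering-pair counts implied by the
    fragment geometry.
    """
    if not 0 < target < 1:
        raise ValueError("target fraction must be in (0, 1)")
    pj = _p_junction(cfg, phage_len, core_len)
    pi = _p_integrated(cfg, lysogen_len, core_len)
    return (target / (1 - target)) * lysogen_weight * lysogen_len * pi / (
        phage_len * pj
    )


def pairs_for_informative_count(n_informative: int, members_geom, cfg: SimConfig,
                                lysogen_len: int, phage_len: int,
                                core_len: int) -> int:
    """n_pairs needed so E[junction + integrated pairs] = n_informative.

    ``members_geom`` is a list of (weight, length, kind) with kind in
    {"lysogen", "cured", "phage"}.
    """
    tot = sum(w * L for w, L, _ in members_geom)
    rate = 0.0
    for w, L, kind in members_geom:
        share = w * L / tot
        if kind == "phage":
            rate += share * _p_junction(cfg, phage_len, core_len)
        elif kind == "lysogen":
            rate += share * _p_integrated(cfg, lysogen_len, core_len)
    if rate <= 0:
        raise ValueError("no informative geometry in the member list")
    return int(np.ceil(n_informative / rate))
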