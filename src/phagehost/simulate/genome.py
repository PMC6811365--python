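"""Host-genome synthesis with planted GC content, GC skew and codon usage.

The chromosome is assembled from CDS back-translated under a genome-wide
codon profile, tRNA genes at requested sites, and intergenic spacers. Two
constraints are built into the sampling itself (no post-hoc editing):

* **GC content.** The codon profile is calibrated (by tilting codon weights
  through a per-base GC parameter solved numerically) so the expected
  coding GC equals the requested genome GC; intergenic bases are sampled at
  the same GC.
* **GC skew.** On the replichore where the forward strand is the leading
  strand (ori -> ter), G is favored over C by ``skew_strength``; the other
  replichore mirrors this. Intergenic bases use the skewed base
  probabilities directly; CDS tilt their synonymous-codon choices by
  ``(1 + s)^nG * (1 - s)^nC`` on the leading strand (sign flipped on the
  lagging strand), which biases codon choice without breaking the encoded
  protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..codonuse import CODONS, SYNONYMOUS_CLASSES
from ..records import Feature, GenomeRecord, revcomp
from .config import SimConfig
from .proteome import AA_ALPHABET, CLASS_ORDER, random_protein

__all__ = [
    "random_codon_profile",
    "host_codon_profile",
    "generate_host_genome",
    "expected_coding_gc",
]

_CODON_GC = np.array([(c.count("G") + c.count("C")) / 3.0 for c in CODONS])
_CODON_G = np.array([c.count("G") for c in CODONS])
_CODON_C = np.array([c.count("C") for c in CODONS])
_CODON_LOOKUP = {c: i for i, c in enumerate(CODONS)}
_AMINO_CLASSES = tuple(aa for aa in CLASS_ORDER if aa != "*")


def _base_weights(q: float, r: float = 0.5) -> np.ndarray:
    """Per-codon weight prod of base probs; P(G)=q*r, P(C)=q*(1-r)."""
    pg = q * r
    pc = q * (1.0 - r)
    pa = (1.0 - q) / 2.0
    w = np.empty(64)
    for i, codon in enumerate(CODONS):
        p = 1.0
        for b in codon:
            p *= pg if b == "G" else pc if b == "C" else pa
        w[i] = p
    return w


def _fractions_from_weights(weights: np.ndarray) -> np.ndarray:
    frac = np.zeros(64)
    for codons in SYNONYMOUS_CLASSES.values():
        ids = [_CODON_LOOKUP[c] for c in codons]
        tot = weights[ids].sum()
        frac[ids] = weights[ids] / tot if tot > 0 else 1.0 / len(ids)
    return frac


def expected_coding_gc(fractions: np.ndarray | pd.Series,
                       aa_freqs: np.ndarray | None = None) -> float:
    """Expected GC of a CDS body under the given amino-acid usage."""
    f = np.asarray(fractions, dtype=float)
    total = 0.0
    for k, aa in enumerate(_AMINO_CLASSES):
        ids = [_CODON_LOOKUP[c] for c in SYNONYMOUS_CLASSES[aa]]
        w = 1.0 / len(_AMINO_CLASSES) if aa_freqs is None else aa_freqs[k]
        total += w * float(np.dot(f[ids], _CODON_GC[ids]))
    return total


def expected_coding_gcskew(fractions: np.ndarray | pd.Series,
                           aa_freqs: np.ndarray | None = None) -> float:
    """Expected per-base (G - C) excess of a CDS body."""
    f = np.asarray(fractions, dtype=float)
    total = 0.0
    for k, aa in enumerate(_AMINO_CLASSES):
        ids = [_CODON_LOOKUP[c] for c in SYNONYMOUS_CLASSES[aa]]
        w = 1.0 / len(_AMINO_CLASSES) if aa_freqs is None else aa_freqs[k]
        total += w * float(np.dot(f[ids], (_CODON_G[ids] - _CODON_C[ids]) / 3.0))
    return total


def _aa_freqs_from_weights(weights: np.ndarray) -> np.ndarray:
    """Amino-acid frequencies implied by summed codon weights per class."""
    w = np.array([
        weights[[_CODON_LOOKUP[c] for c in SYNONYMOUS_CLASSES[aa]]].sum()
        for aa in _AMINO_CLASSES
    ])
    return w / w.sum()


@dataclass(frozen=True)
class CodonProfileModel:
    """A genome's translational signature.

    ``fractions``: synonymous codon fractions over the 64 codons;
    ``aa``: amino-acid frequencies (indexed by the 20 residues in class
    order). Both are jointly calibrated — strongly AT-rich coding is only
    reachable by shifting amino-acid composition, exactly as in real
    low-GC genomes.
    """

    id: str
    fractions: pd.Series
    aa: pd.Series

    def vector(self) -> np.ndarray:
        return self.fractions.to_numpy(dtype=float)


def random_codon_profile(profile_id: str, gc: float,
                         rng: np.random.Generator,
                         concentration: float = 3.0) -> CodonProfileModel:
    """A distinctive codon+AA profile calibrated to a coding GC target.

    Per-codon weights are gamma noise (profile identity) times a base tilt
    with two parameters: the GC level is solved so the expected coding GC
    equals ``gc`` (with amino-acid frequencies implied by the same
    weights), and the G-vs-C balance is solved so the profile carries no
    intrinsic strand skew — planted replication skew, not profile
    identity, controls strand asymmetry.
    """
    noise = rng.gamma(concentration, 1.0, size=64)
    lo, hi = 1e-3, 1.0 - 1e-3

    def model_parts(q: float, r: float):
        w = noise * _base_weights(q, r)
        return _fractions_from_weights(w), _aa_freqs_from_weights(w)

    def solve_q(r: float) -> float:
        def f(q: float) -> float:
            frac, aaw = model_parts(q, r)
            return expected_coding_gc(frac, aaw) - gc
        if f(lo) > 0:
            return lo
        if f(hi) < 0:
            return hi
        return brentq(f, lo, hi, xtol=1e-6)

    def skew_at(r: float) -> float:
        frac, aaw = model_parts(solve_q(r), r)
        return expected_coding_gcskew(frac, aaw)

    if skew_at(lo) > 0:
        r = lo
    elif skew_at(hi) < 0:
        r = hi
    else:
        r = brentq(skew_at, lo, hi, xtol=1e-6)
    frac, aaw = model_parts(solve_q(r), r)
    return CodonProfileModel(
        id=profile_id,
        fractions=pd.Series(frac, index=list(CODONS), name=profile_id),
        aa=pd.Series(aaw, index=list(_AMINO_CLASSES), name=profile_id),
    )


def host_codon_profile(cfg: SimConfig) -> CodonProfileModel:
    """The deterministic planted host profile for a config."""
    rng = cfg.rng("codon_profile:" + cfg.codon_profile_id)
    return random_codon_profile(cfg.codon_profile_id, cfg.gc_fraction, rng)


def sample_protein_from_model(model: CodonProfileModel, length: int,
                              rng: np.random.Generator) -> str:
    """Random protein under the model's amino-acid frequencies."""
    aas = model.aa.index.to_numpy()
    idx = rng.choice(len(aas), size=length, p=model.aa.to_numpy())
    return "".join(aas[idx])


def _skew_tilt(fractions: np.ndarray, s: float) -> np.ndarray:
    """Tilt synonymous choices toward G (s > 0) or C (s < 0)."""
    if s == 0.0:
        return fractions
    mult = (1.0 + abs(s)) ** (_CODON_G if s > 0 else _CODON_C) * \
           (1.0 - abs(s)) ** (_CODON_C if s > 0 else _CODON_G)
    return _fractions_from_weights(fractions * mult)


def _sample_codon_indices(aa_flat: np.ndarray, fractions: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Vectorized synonymous-codon draw for a flat array of AA bytes."""
    out = np.empty(len(aa_flat), dtype=np.int64)
    for aa in _AMINO_CLASSES:
        mask = aa_flat == ord(aa)
        n = int(mask.sum())
        if n == 0:
            continue
        ids = np.array([_CODON_LOOKUP[c] for c in SYNONYMOUS_CLASSES[aa]])
        p = fractions[ids]
        p = p / p.sum() if p.sum() > 0 else np.full(len(ids), 1 / len(ids))
        out[mask] = ids[rng.choice(len(ids), size=n, p=p)]
    return out


_CODON_BYTES = np.array([list(c.encode()) for c in CODONS], dtype=np.uint8)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _sample_intergenic(n: int, leading: np.ndarray, gc: float, s: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample n bases; ``leading[i]`` says the forward strand leads there."""
    pg_lead = gc * (1 + s) / 2
    pc_lead = gc * (1 - s) / 2
    pa = (1 - gc) / 2
    u = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    for is_lead in (True, False):
        m = leading == is_lead
        pg, pc = (pg_lead, pc_lead) if is_lead else (pc_lead, pg_lead)
        edges = np.cumsum([pa, pc, pg, pa])  # A, C, G, T
        out[m] = _BASES[np.searchsorted(edges, u[m], side="right").clip(0, 3)]
    return out


def _is_leading(pos: np.ndarray, ori: int, ter: int, L: int) -> np.ndarray:
    """True where the forward strand is the leading strand (ori -> ter)."""
    a, b = ori % L, ter % L
    if a < b:
        return (pos >= a) & (pos < b)
    return (pos >= a) | (pos < b)


def generate_host_genome(cfg: SimConfig) -> tuple[GenomeRecord, list[Feature]]:
    """Synthesize the host chromosome and its annotations.

    Returns a circular :class:`GenomeRecord` and features (CDS with planted
    protein ids, tRNA genes with anticodon labels). Reproducible bytes for a
    fixed config seed.
    """
    rng = cfg.rng("host_genome")
    L = cfg.genome_length
    model = host_codon_profile(cfg)
    profile = model.vector()
    s = cfg.skew_strength

    trna_seqs = {}
    for pos, label in cfg.trna_sites:
        trna_seqs[(pos, label)] = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=cfg.trna_length)
        )

    # gene lengths (codons, internal) and placement budget
    lengths = np.clip(
        np.round(rng.normal(cfg.mean_cds_codons, cfg.sd_cds_codons, cfg.n_cds)),
        30, None,
    ).astype(int)
    coding_bp = int(((lengths + 2) * 3).sum())
    trna_bp = cfg.trna_length * len(cfg.trna_sites)
    total_gap = L - coding_bp - trna_bp
    if total_gap < 0:
        # deterministic proportional shrink to fit
        scale = (L - trna_bp) / (coding_bp * 1.05)
        lengths = np.maximum((lengths * scale).astype(int), 30)
        coding_bp = int(((lengths + 2) * 3).sum())
        total_gap = L - coding_bp - trna_bp
        if total_gap < 0:
            raise ValueError("CDS set does not fit in genome_length")
    gaps = rng.multinomial(total_gap, np.full(cfg.n_cds + 1, 1 / (cfg.n_cds + 1)))
    strands = np.where(rng.random(cfg.n_cds) < 0.5, 1, -1)

    # lay out blocks: (kind, payload) in genome order
    trna_queue = sorted(trna_seqs.items(), key=lambda kv: kv[0][0])
    blocks: list[tuple[str, object]] = []
    features: list[Feature] = []
    cursor = 0
    ti = 0

    def emit_trna():
        nonlocal cursor, ti
        (pos, label), seq = trna_queue[ti]
        blocks.append(("trna", seq))
        features.append(
            Feature(cursor, cursor + len(seq), "tRNA", 1, f"trna_{ti}",
                    {"anticodon": label, "product": f"tRNA-{label}"})
        )
        cursor += len(seq)
        ti += 1

    gene_blocks: list[tuple[int, int, int]] = []  # (start, n_codons, strand)
    for i in range(cfg.n_cds):
        g = int(gaps[i])
        while ti < len(trna_queue) and trna_queue[ti][0][0] <= cursor + g:
            blocks.append(("gap", g))
            cursor += g
            g = 0
            emit_trna()
        if g:
            blocks.append(("gap", g))
            cursor += g
        n_codon = int(lengths[i])
        bp = (n_codon + 2) * 3
        blocks.append(("cds", i))
        gene_blocks.append((cursor, n_codon, int(strands[i])))
        features.append(
            Feature(cursor, cursor + bp, "CDS", int(strands[i]), f"cds_{i:05d}",
                    {"product": "hypothetical protein"})
        )
        cursor += bp
    blocks.append(("gap", int(gaps[-1])))
    cursor += int(gaps[-1])
    while ti < len(trna_queue):
        emit_trna()
    assert cursor == L, (cursor, L)

    # back-translate all genes, grouped by skew-tilt sign
    proteins = [sample_protein_from_model(model, n, rng)
                for _, n, _ in gene_blocks]
    mids = np.array([st + (n + 2) * 3 // 2 for st, n, _ in gene_blocks])
    leading = _is_leading(mids, cfg.ori_position, cfg.ter_position, L)
    gene_strand = np.array([sd for _, _, sd in gene_blocks])
    # coding strand leads <=> (forward leads) == (gene on forward strand)
    tilt_sign = np.where(leading == (gene_strand > 0), s, -s)

    gene_seqs: list[str | None] = [None] * len(gene_blocks)
    for sign in sorted(set(tilt_sign.tolist())):
        frac = _skew_tilt(profile, float(sign))
        idxs = [i for i in range(len(gene_blocks)) if tilt_sign[i] == sign]
        aa_flat = np.frombuffer("".join(proteins[i] for i in idxs).encode(),
                                dtype=np.uint8)
        codon_idx = _sample_codon_indices(aa_flat, frac, rng)
        stops = SYNONYMOUS_CLASSES["*"]
        stop_ids = np.array([_CODON_LOOKUP[c] for c in stops])
        stop_p = frac[stop_ids]
        stop_p = stop_p / stop_p.sum() if stop_p.sum() > 0 else np.full(3, 1 / 3)
        stop_draws = stop_ids[rng.choice(3, size=len(idxs), p=stop_p)]
        off = 0
        codon_strs = np.array(CODONS)
        for j, i in enumerate(idxs):
            n = len(proteins[i])
            body = "".join(codon_strs[codon_idx[off:off + n]])
            off += n
            cds = "ATG" + body + str(codon_strs[stop_draws[j]])
            gene_seqs[i] = cds if gene_strand[i] > 0 else revcomp(cds)

    # assemble the chromosome
    parts: list[str] = []
    gi = 0
    cursor = 0
    for kind, payload in blocks:
        if kind == "gap":
            n = int(payload)  # type: ignore[arg-type]
            if n:
                pos = np.arange(cursor, cursor + n)
                lead = _is_leading(pos, cfg.ori_position, cfg.ter_position, L)
                parts.append(
                    _sample_intergenic(n, lead, cfg.gc_fraction, s, rng)
                    .tobytes().decode()
                )
            cursor += n
        elif kind == "trna":
            parts.append(payload)  # type: ignore[arg-type]
            cursor += len(payload)  # type: ignore[arg-type]
        else:  # cds
            seq = gene_seqs[gi]
            parts.append(seq)  # type: ignore[arg-type]
            cursor += len(seq)  # type: ignore[arg-type]
            gi += 1
    genome = "".join(parts)
    assert len(genome) == L
    rec = GenomeRecord(id="synthetic_host", seq=genome, circular=True)
    return rec, features
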