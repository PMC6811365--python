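"""Protein and CDS generation under codon-usage profiles.

CDS are produced by back-translating amino-acid sequences under a codon
profile (translation table 11, no introns): each amino acid draws one of
its synonymous codons with the profile's class fractions. A phage proteome
is generated from a host profile blended toward the uniform synonymous
distribution by a ``divergence`` parameter, emulating the partial
adaptation of phage codon usage to the host translation machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..codonuse import CODONS, SYNONYMOUS_CLASSES

__all__ = [
    "AA_ALPHABET",
    "random_protein",
    "mutate_protein",
    "sample_codons",
    "back_translate",
    "blend_profile",
    "uniform_profile",
    "generate_phage_proteome",
]

#: the 20 standard amino acids
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: iteration order over synonymous classes (stable for RNG determinism)
CLASS_ORDER: tuple[str, ...] = tuple(sorted(SYNONYMOUS_CLASSES))


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition random protein of ``length`` residues."""
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return "".join(AA_ALPHABET[i] for i in idx)


def mutate_protein(protein: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute ``n_subs`` distinct positions with a different residue."""
    if n_subs == 0:
        return protein
    arr = list(protein)
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        choices = [a for a in AA_ALPHABET if a != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def uniform_profile() -> pd.Series:
    """Uniform synonymous fractions within every class."""
    frac = pd.Series(0.0, index=list(CODONS))
    for codons in SYNONYMOUS_CLASSES.values():
        frac[list(codons)] = 1.0 / len(codons)
    return frac


def blend_profile(host: pd.Series, divergence: float) -> pd.Series:
    """(1 - d) * host + d * uniform-within-class; d in [0, 1]."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    return (1.0 - divergence) * host + divergence * uniform_profile()


def sample_codons(protein: str, fractions: pd.Series,
                  rng: np.random.Generator,
                  add_start_stop: bool = True) -> str:
    """Back-translate one protein; optionally wrap with ATG ... stop."""
    return back_translate([protein], fractions, rng, add_start_stop)[0]


def back_translate(proteins: list[str], fractions: pd.Series,
                   rng: np.random.Generator,
                   add_start_stop: bool = True) -> list[str]:
    """Back-translate proteins under class fractions (vectorized per class)."""
    frac = fractions.reindex(list(CODONS)).to_numpy(dtype=float)
    lengths = [len(p) for p in proteins]
    flat = "".join(proteins)
    aa_arr = np.frombuffer(flat.encode(), dtype=np.uint8)
    codon_idx = np.empty(len(flat), dtype=np.int64)
    codon_lookup = {c: i for i, c in enumerate(CODONS)}
    for aa in CLASS_ORDER:
        if aa == "*":
            continue
        mask = aa_arr == ord(aa)
        n = int(mask.sum())
        if n == 0:
            continue
        codons = SYNONYMOUS_CLASSES[aa]
        ids = np.array([codon_lookup[c] for c in codons])
        p = frac[ids]
        total = p.sum()
        p = np.full(len(ids), 1.0 / len(ids)) if total <= 0 else p / total
        codon_idx[mask] = ids[rng.choice(len(ids), size=n, p=p)]
    codon_strs = np.array(CODONS)
    flat_codons = codon_strs[codon_idx]
    out = []
    offset = 0
    stop_ids = np.array([codon_lookup[c] for c in SYNONYMOUS_CLASSES["*"]])
    stop_p = frac[stop_ids]
    stop_p = (np.full(3, 1 / 3) if stop_p.sum() <= 0 else stop_p / stop_p.sum())
    for L in lengths:
        body = "".join(flat_codons[offset:offset + L])
        offset += L
        if add_start_stop:
            stop = CODONS[stop_ids[rng.choice(3, p=stop_p)]]
            body = "ATG" + body + stop
        out.append(body)
    return out


def generate_phage_proteome(host_profile, n_genes: int,
                            divergence: float,
                            seed: int | np.random.Generator = 0,
                            mean_codons: int = 200,
                            sd_codons: int = 60) -> list[str]:
    """CDS set whose codon usage sits ``divergence`` of the way from the
    host profile to the uniform synonymous distribution.

    ``host_profile`` is either a 64-codon fraction Series or a calibrated
    profile model (whose amino-acid frequencies are then also used for the
    emitted proteins). At divergence 0 the emitted usage converges to the
    host profile with gene-set size; at divergence 1 it is uniform over
    synonymous codons.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fractions = getattr(host_profile, "fractions", host_profile)
    aa_freqs = getattr(host_profile, "aa", None)
    profile = blend_profile(fractions, divergence)
    lengths = np.clip(
        np.round(rng.normal(mean_codons, sd_codons, size=n_genes)), 30, None
    ).astype(int)
    if aa_freqs is None:
        proteins = [random_protein(int(L), rng) for L in lengths]
    else:
        aas = aa_freqs.index.to_numpy()
        p = aa_freqs.to_numpy()
        proteins = ["".join(aas[rng.choice(len(aas), size=int(L), p=p)])
                    for L in lengths]
    return back_translate(proteins, profile, rng, add_start_stop=True)
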