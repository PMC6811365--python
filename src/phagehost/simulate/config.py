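"""Simulation configuration and ground-truth records."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SimConfig", "SyntheticTruth"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic lysogen community.

    Defaults mirror the system the pipeline was built around: a ~1.14-Mb
    low-GC (29.6%) freshwater SAR11-like host with bidirectional
    replication, a ~39.4-kb temperate phage (GC 32.1%) integrated at a
    tRNA-Leu(TAG) gene duplicating an 11-bp core into attL/attR, paired-end
    150-bp reads, and a read pool mixing lysogens, prophage-free cells and
    free circular phage. Tests and drivers pass scaled-down copies via
    ``scaled``; the structure, not the size, is what downstream stages rely
    on.
    """

    seed: int = 0
    genome_length: int = 1_136_868
    gc_fraction: float = 0.296
    ori_position: int = 0
    ter_position: int = 568_434
    skew_strength: float = 0.5
    n_cds: int = 1_229
    codon_profile_id: str = "host"
    trna_sites: tuple[tuple[int, str], ...] = ((340_000, "Leu(TAG)"),)
    trna_length: int = 85
    core_length: int = 11
    phage_length: int = 39_413
    phage_gc: float = 0.321
    phage_n_cds: int = 52
    phage_divergence: float = 0.05
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 35
    n_pairs: int = 100_000
    error_rate: float = 0.001
    mixture: tuple[float, float, float] = (0.75, 0.20, 0.05)  # lysogen, prophage-free, free phage
    mean_cds_codons: int = 300
    sd_cds_codons: int = 80

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        if self.ori_position == self.ter_position:
            raise ValueError("ori and ter must differ")
        if self.core_length < 1:
            raise ValueError("core_length must be >= 1")
        for name in ("genome_length", "phage_length", "read_length",
                     "insert_mean", "trna_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.skew_strength <= 1.0:
            raise ValueError("skew_strength must be in [0, 1]")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.core_length > self.trna_length:
            raise ValueError("core_length cannot exceed the tRNA gene length")
        mean_cds_bp = (self.mean_cds_codons + 2) * 3
        if self.n_cds * mean_cds_bp > self.genome_length:
            raise ValueError(
                f"{self.n_cds} CDS x ~{mean_cds_bp} bp exceed genome_length"
            )

    def scaled(self, **overrides) -> "SimConfig":
        """Copy with overrides (convenience for scaled-down test configs)."""
        return replace(self, **overrides)

    def rng(self, stream: str = "") -> np.random.Generator:
        """Named deterministic RNG stream derived from the seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    Only the fields relevant to a given generator are populated.
    """

    # prophage / lysogen truth
    attL: tuple[int, int] | None = None
    attR: tuple[int, int] | None = None
    core: str | None = None
    phage_start_offset: int | None = None
    integration_anticodon: str | None = None
    core_is_degenerate: bool = False  # core occurs beyond the two att copies

    # read-pool truth
    circularizing_fraction: float | None = None

    # codon-usage truth
    codon_profile_ids: dict[str, str] = field(default_factory=dict)

    # marker-dataset truth
    presence: "object | None" = None  # genotype x sample boolean DataFrame
    coverages: "object | None" = None  # genotype x sample float DataFrame
    abundances: "object | None" = None  # per-sample truth percentages
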