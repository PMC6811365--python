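"""Synthetic lysogens: phage genomes, tRNA-site integration, scenarios.

Integration follows the att-site convention of tailed temperate phage that
target tRNA genes: the phage attachment site carries a copy of the last
``core_length`` bases of the host tRNA (the "core"), so recombination
leaves an intact tRNA ending at *attL* and duplicates the core at *attR*.
The phage also carries its own tRNA body immediately upstream of its core
copy, so the *attR*-side copy reconstitutes a complete tRNA gene — the
"replacement tRNA" arrangement observed in real tRNA-integrating
prophages. Free phage are circular and start at the core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..records import Feature, GenomeRecord
from .config import SimConfig, SyntheticTruth
from .genome import (
    _sample_intergenic,
    generate_host_genome,
    host_codon_profile,
)
from .proteome import generate_phage_proteome

logger = logging.getLogger(__name__)

__all__ = [
    "generate_phage_genome",
    "insert_prophage",
    "ProphageScenario",
    "build_prophage_scenario",
]


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_phage_genome(cfg: SimConfig, core: str, trna_seq: str,
                          host_profile: pd.Series,
                          rng: np.random.Generator,
                          avoid_next_base: str | None = None,
                          trna_body_divergence: float = 0.15) -> GenomeRecord:
    """A circular phage genome starting at the att core.

    Layout: ``core | guard | CDS + spacers | tRNA body`` — the trailing
    tRNA body (a *diverged homolog* of the host tRNA minus its terminal
    core) wraps through the leading core to form the phage's own complete
    tRNA copy. Only the core itself is kept identical to the host: the
    body's terminal base is forced to differ, and the guard base after the
    core is forced to differ from ``avoid_next_base`` (the host base after
    the tRNA), so the att core is exactly the maximal identical repeat in
    the lysogen — as in real tRNA-integrating systems, where the shared
    core is defined as the maximal identity stretch.
    """
    c = len(core)
    body_orig = trna_seq[: len(trna_seq) - c]
    body_arr = list(body_orig)
    for i in range(len(body_arr)):
        if rng.random() < trna_body_divergence:
            body_arr[i] = _other_base(body_arr[i], rng)
    if body_arr and body_arr[-1] == body_orig[-1]:
        body_arr[-1] = _other_base(body_orig[-1], rng)
    body = "".join(body_arr)
    guard = ("ACGT"[rng.integers(0, 4)] if avoid_next_base is None
             else _other_base(avoid_next_base, rng))
    available = cfg.phage_length - c - len(body) - 1
    if available <= 0:
        raise ValueError("phage_length too small for core + tRNA body")
    # target ~88% coding density
    mean_codons = max(30, int(available * 0.88 / (cfg.phage_n_cds * 3)) - 2)
    cds = generate_phage_proteome(
        host_profile, cfg.phage_n_cds, cfg.phage_divergence, rng,
        mean_codons=mean_codons, sd_codons=max(5, mean_codons // 5),
    )
    coding = sum(len(s) for s in cds)
    gap_total = available - coding
    while gap_total < 0:  # drop genes that do not fit (rare)
        cds = cds[:-1]
        coding = sum(len(s) for s in cds)
        gap_total = available - coding
    gaps = rng.multinomial(gap_total, np.full(len(cds) + 1, 1 / (len(cds) + 1)))
    parts = [core, guard]
    cursor = c + 1
    features: list[Feature] = []
    for i, g in enumerate(gaps):
        if g:
            lead = np.ones(int(g), dtype=bool)
            parts.append(
                _sample_intergenic(int(g), lead, cfg.phage_gc, 0.0, rng)
                .tobytes().decode()
            )
            cursor += int(g)
        if i < len(cds):
            parts.append(cds[i])
            features.append(
                Feature(cursor, cursor + len(cds[i]), "CDS", 1,
                        f"phage_cds_{i:04d}",
                        {"product": "phage hypothetical protein"})
            )
            cursor += len(cds[i])
    parts.append(body)
    seq = "".join(parts)
    assert len(seq) == cfg.phage_length, (len(seq), cfg.phage_length)
    if seq.count(core) > 1:
        logger.warning("att core occurs inside the phage body (degenerate case)")
    return GenomeRecord(id="synthetic_phage", seq=seq, circular=True), features


def insert_prophage(host: GenomeRecord, phage: GenomeRecord,
                    trna_site: Feature, core_length: int,
                    ) -> tuple[GenomeRecord, SyntheticTruth]:
    """Integrate ``phage`` at the 3' end of a host tRNA gene.

    The last ``core_length`` bases of the tRNA become the shared core; the
    lysogen is ``host[:t1] + phage[c:] + core + host[t1:]`` for a phage
    rotated to start at the core, which places identical direct repeats at
    attL = [t1-c, t1) and attR = [t1-c+P, t1+P).
    """
    if trna_site.type != "tRNA":
        raise ValueError("integration site must be a tRNA feature")
    c = core_length
    if c > trna_site.length:
        raise ValueError("core_length exceeds tRNA gene length")
    t1 = trna_site.end
    core = host.seq[t1 - c: t1]
    idx = phage.seq.find(core)
    if idx < 0:
        raise ValueError("phage genome does not carry the att core")
    ph = phage if idx == 0 else replace(phage, seq=phage.seq[idx:] + phage.seq[:idx])
    P = len(ph.seq)
    lysogen_seq = host.seq[:t1] + ph.seq[c:] + core + host.seq[t1:]
    attL = (t1 - c, t1)
    attR = (t1 - c + P, t1 + P)
    n_occ = lysogen_seq.count(core)
    degenerate = n_occ > 2
    if degenerate:
        logger.warning(
            "core %r occurs %d times in the lysogen (detector ambiguity)",
            core, n_occ,
        )
    lysogen = GenomeRecord(id=host.id + "_lysogen", seq=lysogen_seq, circular=True)
    truth = SyntheticTruth(
        attL=attL, attR=attR, core=core, phage_start_offset=idx,
        integration_anticodon=trna_site.attributes.get("anticodon"),
        core_is_degenerate=degenerate,
    )
    assert len(lysogen_seq) == len(host.seq) + P
    return lysogen, truth


@dataclass
class ProphageScenario:
    """A complete synthetic lysogen system with ground truth."""

    cfg: SimConfig
    host: GenomeRecord
    host_features: list[Feature]
    phage: GenomeRecord
    lysogen: GenomeRecord
    lysogen_features: list[Feature]
    truth: SyntheticTruth
    host_profile: object  # CodonProfileModel
    trna_feature: Feature
    phage_features: list[Feature] | None = None

    @property
    def att_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.truth.attL, self.truth.attR  # type: ignore[return-value]


def _shift_features(features: list[Feature], at: int, by: int) -> list[Feature]:
    out = []
    for f in features:
        if f.start >= at:
            out.append(replace(f, start=f.start + by, end=f.end + by))
        else:
            out.append(f)
    return out


def build_prophage_scenario(cfg: SimConfig) -> ProphageScenario:
    """Generate host, phage and lysogen with consistent annotations."""
    host, host_features = generate_host_genome(cfg)
    profile = host_codon_profile(cfg)
    trnas = [f for f in host_features if f.type == "tRNA"]
    if not trnas:
        raise ValueError("host has no tRNA site to integrate at")
    site = trnas[0]
    rng = cfg.rng("phage_genome")
    trna_seq = host.seq[site.start: site.end]
    avoid = host.seq[site.end] if site.end < len(host.seq) else host.seq[0]
    phage, phage_features = generate_phage_genome(
        cfg, host.seq[site.end - cfg.core_length: site.end],
        trna_seq, profile, rng, avoid_next_base=avoid)
    lysogen, truth = insert_prophage(host, phage, site, cfg.core_length)
    P = len(phage.seq)
    lys_features = _shift_features(host_features, site.end, P)
    # phage coordinates p (>= core) map to lysogen t1 + (p - core_length)
    for f in phage_features:
        lys_features.append(replace(
            f, start=site.end + f.start - cfg.core_length,
            end=site.end + f.end - cfg.core_length,
        ))
    # the phage's own tRNA copy ends exactly at the attR core end
    t1 = site.end
    tau = cfg.trna_length
    lys_features.append(
        Feature(t1 + P - tau, t1 + P, "tRNA", 1, "trna_phage",
                {"anticodon": site.attributes.get("anticodon", ""),
                 "product": "phage tRNA copy"})
    )
    return ProphageScenario(
        cfg=cfg, host=host, host_features=host_features, phage=phage,
        lysogen=lysogen, lysogen_features=lys_features, truth=truth,
        host_profile=profile, trna_feature=site,
        phage_features=phage_features,
    )


def community_members(scenario: ProphageScenario,
                      weights: tuple[float, float, float] | None = None):
    """MemberSpecs (lysogen, prophage-free host, free circular phage).

    Weights default to the config mixture. Block maps project each member
    onto lysogen coordinates for the idealized alignment table; zero-weight
    members are dropped.
    """
    from .reads import MemberSpec

    cfg = scenario.cfg
    w = weights if weights is not None else cfg.mixture
    (s1, _), (s2, _) = scenario.truth.attL, scenario.truth.attR
    c = cfg.core_length
    L_lys = len(scenario.lysogen.seq)
    L_host = len(scenario.host.seq)
    excised = scenario.lysogen.seq[s1:s2]
    members = []
    if w[0] > 0:
        members.append(MemberSpec(scenario.lysogen, w[0], circular=False,
                                  blocks=[(0, L_lys, 0)], dup=0))
    if w[1] > 0:
        members.append(MemberSpec(
            scenario.host, w[1], circular=False,
            blocks=[(0, s1, 0), (s1, L_host, s2)], dup=c,
        ))
    if w[2] > 0:
        from ..records import GenomeRecord

        free = GenomeRecord("free_phage", excised, circular=True)
        members.append(MemberSpec(free, w[2], circular=True,
                                  blocks=[(0, len(excised), s1)], dup=c))
    return members
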