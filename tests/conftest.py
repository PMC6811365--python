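"""Shared fixtures: scaled-down synthetic systems built once per session."""

from __future__ import annotations

import pytest

from phagehost.simulate import SimConfig, build_prophage_scenario


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A desk-scale lysogen system (60-kb host, 15-kb phage)."""
    base = dict(
        genome_length=60_000,
        n_cds=55,
        ori_position=0,
        ter_position=30_000,
        trna_sites=((20_000, "Leu(TAG)"),),
        phage_length=15_000,
        phage_n_cds=18,
        read_length=100,
        insert_mean=320,
        insert_sd=30,
        n_pairs=20_000,
    )
    base.update(overrides)
    return SimConfig(seed=seed).scaled(**base)


@pytest.fixture(scope="session")
def scenario():
    """One fully built synthetic lysogen scenario (seed 1)."""
    return build_prophage_scenario(small_config(seed=1))


@pytest.fixture(scope="session")
def scenario_alt():
    """A second scenario with different geometry (seed 5)."""
    return build_prophage_scenario(
        small_config(seed=5, genome_length=50_000, n_cds=45,
                     ter_position=25_000, trna_sites=((33_000, "Arg(TCT)"),),
                     phage_length=12_000, phage_n_cds=14)
    )
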