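#!/usr/bin/env python
"""Simulate the study system: a lysogen community with known ground truth.

Generates a bacterial host chromosome with bidirectional-replication GC
skew and a planted codon-usage signature, integrates a temperate phage at
the host tRNA-Leu(TAG) site (11-bp core duplicated into attL/attR), and
simulates a paired-end read pool mixing lysogens, prophage-free cells and
free circular phage — with the free-phage weight planted so that 5% of
informative read pairs support the circular form.

Large artifacts (FASTA, GFF3, alignment table) go to scratch/analysis/;
a small run manifest with the full configuration and truth goes to
results/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np

from phagehost.records import write_fasta, write_gff3
from phagehost.simulate import SimConfig, build_prophage_scenario, simulate_reads
from phagehost.simulate.prophage import community_members
from phagehost.simulate.reads import (
    pairs_for_informative_count,
    weights_for_circularizing_fraction,
    write_alignment_tsv,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.scratch.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    # desk-scale geometry; the structure, not the size, carries the signal
    cfg = SimConfig(seed=args.seed).scaled(
        genome_length=50_000, n_cds=45, ter_position=25_000,
        trna_sites=((18_000, "Leu(TAG)"),), phage_length=12_000,
        phage_n_cds=15, read_length=100, insert_mean=320, insert_sd=30,
    )
    sc = build_prophage_scenario(cfg)
    print(f"host {len(sc.host):,} bp | phage {len(sc.phage):,} bp | "
          f"lysogen {len(sc.lysogen):,} bp")
    print(f"att core: {sc.truth.core} ({len(sc.truth.core)} bp) at "
          f"attL={sc.truth.attL} attR={sc.truth.attR}")

    wl, wc = 1.0, 0.3
    wp = weights_for_circularizing_fraction(
        0.05, len(sc.lysogen), cfg.phage_length, cfg.core_length, cfg, wl)
    geom = [(wl, len(sc.lysogen), "lysogen"), (wc, len(sc.host), "cured"),
            (wp, cfg.phage_length, "phage")]
    n_pairs = pairs_for_informative_count(
        2_100, geom, cfg, len(sc.lysogen), cfg.phage_length, cfg.core_length)
    pool = simulate_reads(community_members(sc, (wl, wc, wp)),
                          cfg.scaled(n_pairs=n_pairs),
                          rng=np.random.default_rng(args.seed))
    print(f"simulated {n_pairs:,} read pairs "
          f"(planted circularizing fraction 5%)")

    write_fasta([sc.host], args.scratch / "host.fasta")
    write_fasta([sc.phage], args.scratch / "phage.fasta")
    write_fasta([sc.lysogen], args.scratch / "lysogen.fasta")
    write_gff3(sc.lysogen_features, sc.lysogen.id,
               args.scratch / "lysogen.gff3")
    write_alignment_tsv(pool, args.scratch / "alignments.tsv")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "weights": {"lysogen": wl, "prophage_free": wc, "free_phage": wp},
        "n_pairs": n_pairs,
        "truth": {
            "attL": sc.truth.attL, "attR": sc.truth.attR,
            "core": sc.truth.core,
            "integration_anticodon": sc.truth.integration_anticodon,
            "planted_circularizing_fraction": 0.05,
        },
    }
    out = args.results / "01_simulation_manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    print(f"wrote {out} and FASTA/GFF3/alignments under {args.scratch}/")


if __name__ == "__main__":
    main()
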