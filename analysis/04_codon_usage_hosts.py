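#!/usr/bin/env python
"""Predict phage hosts by codon-usage clustering.

Builds a community of four bacterial genomes with distinct planted codon
profiles plus one phage whose codon usage is adapted to one host
(divergence 0.1), computes per-genome synonymous codon fractions, clusters
them (Euclidean, UPGMA) and reads the phage's host candidates off the
flat clusters.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from phagehost.codonuse import cluster_profiles, predict_hosts, profile_from_cds
from phagehost.simulate.genome import random_codon_profile
from phagehost.simulate.proteome import generate_phage_proteome


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    hosts = {f"host_{k}": random_codon_profile(
        f"h{k}", 0.35, np.random.default_rng(args.seed * 100 + k))
        for k in range(4)}
    profs = []
    for j, (name, model) in enumerate(sorted(hosts.items())):
        cds = generate_phage_proteome(model, 60, 0.0,
                                      np.random.default_rng(args.seed * 7 + j),
                                      mean_codons=250)
        profs.append(profile_from_cds(cds, name))
    phage_cds = generate_phage_proteome(hosts["host_0"], 40, 0.1,
                                        np.random.default_rng(args.seed),
                                        mean_codons=180)
    profs.append(profile_from_cds(phage_cds, "phage_X"))

    clustering = cluster_profiles(profs)
    candidates = predict_hosts(clustering, ["phage_X"])
    print("host candidates for phage_X:", candidates["phage_X"])
    print("(true host: host_0)")

    table = pd.DataFrame({p.genome_id: p.fractions for p in profs}).T
    table.to_csv(args.results / "04_codon_usage_profiles.tsv", sep="\t",
                 float_format="%.5f")
    clustering.distances.to_csv(args.results / "04_profile_distances.tsv",
                                sep="\t", float_format="%.5f")
    (args.results / "04_dendrogram.nwk").write_text(
        clustering.to_newick() + "\n")
    with open(args.results / "04_host_candidates.json", "w") as fh:
        json.dump(candidates, fh, indent=2)
    print(f"wrote profiles, distances, dendrogram and candidates "
          f"under {args.results}/")


if __name__ == "__main__":
    main()
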