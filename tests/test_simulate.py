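"""Synthetic-data generators: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phagehost.codonuse import profile_from_cds
from phagehost.records import read_fasta, read_gff3, revcomp, write_fasta, write_gff3
from phagehost.simulate import (
    SimConfig,
    build_prophage_scenario,
    generate_host_genome,
    generate_phage_proteome,
    insert_prophage,
    simulate_reads,
)
from phagehost.simulate.genome import host_codon_profile, random_codon_profile
from phagehost.simulate.markers import generate_marker_dataset, make_genotype_pool
from phagehost.simulate.prophage import community_members
from phagehost.simulate.reads import (
    MemberSpec,
    reads_to_fastq,
    read_alignment_tsv,
    weights_for_circularizing_fraction,
    write_alignment_tsv,
)
from phagehost.seqstats import gc_content
from phagehost.prophage import AttPair, excise_prophage, score_read_evidence

from conftest import small_config


class TestSimConfig:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="mixture"):
            SimConfig(mixture=(0.5, 0.4, 0.2))

    def test_ori_ter_must_differ(self):
        with pytest.raises(ValueError, match="ori and ter"):
            SimConfig(ori_position=5, ter_position=5)

    def test_cds_budget_checked(self):
        with pytest.raises(ValueError, match="exceed genome_length"):
            small_config(genome_length=20_000, n_cds=100)

    def test_insert_must_cover_read(self):
        with pytest.raises(ValueError, match="insert_mean"):
            small_config(insert_mean=80, read_length=100)


class TestHostGenome:
    def test_gc_fraction_within_tolerance(self, scenario):
        assert abs(gc_content(scenario.host) - scenario.cfg.gc_fraction) < 0.01

    def test_same_seed_same_bytes(self, tmp_path):
        cfg = small_config(seed=7)
        r1, _ = generate_host_genome(cfg)
        r2, _ = generate_host_genome(cfg)
        assert r1.seq == r2.seq
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta([r1], p1)
        write_fasta([r2], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        a, _ = generate_host_genome(small_config(seed=7))
        b, _ = generate_host_genome(small_config(seed=8))
        assert a.seq != b.seq

    def test_requested_trna_annotated(self, scenario):
        trnas = [f for f in scenario.host_features if f.type == "tRNA"]
        assert len(trnas) == 1
        assert trnas[0].attributes["anticodon"] == "Leu(TAG)"
        assert sum(f.type == "CDS" for f in scenario.host_features) == \
            scenario.cfg.n_cds

    def test_gff3_round_trip(self, scenario, tmp_path):
        path = tmp_path / "host.gff3"
        write_gff3(scenario.host_features, scenario.host.id, path)
        feats = read_gff3(path)
        assert len(feats) == len(scenario.host_features)
        orig = sorted((f.start, f.end, f.type) for f in scenario.host_features)
        back = sorted((f.start, f.end, f.type) for f in feats)
        assert orig == back


class TestInsertProphage:
    def test_length_conservation(self, scenario):
        assert len(scenario.lysogen) == len(scenario.host) + len(scenario.phage)

    def test_att_cores_identical_direct_repeats(self, scenario):
        t = scenario.truth
        (l0, l1), (r0, r1) = t.attL, t.attR
        seq = scenario.lysogen.seq
        assert seq[l0:l1] == seq[r0:r1] == t.core
        assert len(t.core) == scenario.cfg.core_length == 11

    def test_round_trip_recovers_host_and_phage(self, scenario):
        att = AttPair(scenario.truth.attL, scenario.truth.attR,
                      scenario.truth.core)
        cured, phage = excise_prophage(scenario.lysogen, att)
        assert cured.seq == scenario.host.seq
        assert phage.seq in scenario.phage.seq + scenario.phage.seq  # rotation

    def test_core_must_be_on_phage(self, scenario):
        from phagehost.records import GenomeRecord

        alien = GenomeRecord("x", "ACGT" * 1000, circular=True)
        with pytest.raises(ValueError, match="core"):
            insert_prophage(scenario.host, alien, scenario.trna_feature, 11)


class TestReadSimulation:
    def test_single_linear_member_yields_no_clips_or_eversion(self, scenario):
        cfg = scenario.cfg.scaled(n_pairs=2_000)
        members = community_members(scenario, (1.0, 0, 0))[:1]
        pool = simulate_reads(members, cfg, rng=np.random.default_rng(0))
        aln = pool.alignments
        assert (aln["clip_left"] == 0).all() and (aln["clip_right"] == 0).all()
        att = AttPair(scenario.truth.attL, scenario.truth.attR,
                      scenario.truth.core)
        ev = score_read_evidence(scenario.lysogen, att, aln)
        assert ev.n_junction_pairs == 0
        assert ev.n_attB_spanning_pairs == 0

    def test_error_free_reads_are_exact_substrings(self, scenario):
        cfg = scenario.cfg.scaled(n_pairs=150, error_rate=0.0)
        members = community_members(scenario, (0.6, 0.2, 0.2))
        pool = simulate_reads(members, cfg, rng=np.random.default_rng(1),
                              with_sequences=True)
        texts = [m.record.seq + (m.record.seq[:cfg.read_length]
                                 if m.circular else "")
                 for m in members]
        for row in pool.sequences.itertuples():
            s = row.seq
            assert any(s in t or revcomp(s) in t for t in texts)

    def test_determinism_and_tsv_round_trip(self, scenario, tmp_path):
        cfg = scenario.cfg.scaled(n_pairs=500)
        members = community_members(scenario, (0.7, 0.2, 0.1))
        p1 = simulate_reads(members, cfg, rng=np.random.default_rng(42))
        p2 = simulate_reads(members, cfg, rng=np.random.default_rng(42))
        pd.testing.assert_frame_equal(p1.alignments, p2.alignments)
        path = tmp_path / "aln.tsv"
        write_alignment_tsv(p1, path)
        back = read_alignment_tsv(path)
        for col in ["read_id", "mate", "pos", "strand", "nm", "m_len",
                    "clip_left", "clip_right"]:
            assert (back[col].to_numpy() ==
                    p1.alignments[col].to_numpy()).all(), col

    def test_fastq_output_deterministic(self, scenario, tmp_path):
        cfg = scenario.cfg.scaled(n_pairs=50)
        members = community_members(scenario, (1.0, 0, 0))[:1]
        out = []
        for tag in ("a", "b"):
            pool = simulate_reads(members, cfg, rng=np.random.default_rng(3),
                                  with_sequences=True)
            r1, r2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            reads_to_fastq(pool, r1, r2)
            out.append(r1.read_bytes() + r2.read_bytes())
        assert out[0] == out[1]

    def test_planted_circularizing_fraction_in_binomial_interval(self, scenario):
        # binomial oracle at the planted 5% rate
        cfg = scenario.cfg
        L_lys, P, c = (len(scenario.lysogen), cfg.phage_length,
                       cfg.core_length)
        wp = weights_for_circularizing_fraction(0.05, L_lys, P, c, cfg)
        members = community_members(scenario, (1.0, 0.2, wp))
        from phagehost.simulate.reads import pairs_for_informative_count

        geom = [(1.0, L_lys, "lysogen"), (0.2, len(scenario.host), "cured"),
                (wp, P, "phage")]
        n_pairs = pairs_for_informative_count(900, geom, cfg, L_lys, P, c)
        pool = simulate_reads(members, cfg.scaled(n_pairs=n_pairs),
                              rng=np.random.default_rng(11))
        att = AttPair(scenario.truth.attL, scenario.truth.attR,
                      scenario.truth.core)
        ev = score_read_evidence(scenario.lysogen, att, pool.alignments)
        n = ev.n_junction_pairs + ev.n_integrated_pairs
        lo, hi = stats.binom.interval(0.999, n, 0.05)
        assert lo <= ev.n_junction_pairs <= hi

    def test_weight_must_be_positive(self, scenario):
        with pytest.raises(ValueError):
            MemberSpec(scenario.host, 0.0)


class TestPhageProteome:
    def test_zero_divergence_converges_to_host_profile(self):
        rng = np.random.default_rng(0)
        host = random_codon_profile("h", 0.35, np.random.default_rng(1))
        decoys = [random_codon_profile(f"d{k}", 0.35,
                                       np.random.default_rng(10 + k))
                  for k in range(3)]
        cds = generate_phage_proteome(host, 80, 0.0, rng, mean_codons=250)
        emitted = profile_from_cds(cds, "phage").vector()
        d_host = np.linalg.norm(emitted - host.vector())
        for d in decoys:
            assert d_host < np.linalg.norm(emitted - d.vector())

    def test_empty_proteome_rejected(self):
        host = random_codon_profile("h", 0.4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_phage_proteome(host, 0, 0.1)

    def test_fixed_seed_reproducible(self):
        host = random_codon_profile("h", 0.4, np.random.default_rng(0))
        a = generate_phage_proteome(host, 5, 0.2, seed=9)
        b = generate_phage_proteome(host, 5, 0.2, seed=9)
        assert a == b


class TestMarkerDataset:
    def test_phage_implies_host_enforced(self):
        pool = make_genotype_pool(seed=0)
        table, truth = generate_marker_dataset(500, pool, seed=3)
        pres = truth.presence
        phage = [g.genotype_id for g in pool if g.role == "phage"]
        target = [g.genotype_id for g in pool if g.role == "target"]
        phage_pos = pres.loc[phage].any(axis=0)
        host_pos = pres.loc[target].any(axis=0)
        assert not (phage_pos & ~host_pos).any()

    def test_equal_coverage_gives_100_over_k(self):
        # one sample, k genotypes at equal coverage, one target genotype
        from phagehost.markers import relative_abundance

        cov = {f"g{i}": 2.5 for i in range(5)}
        res = relative_abundance(cov, ["g0"], [])
        assert res.taxon_pct == pytest.approx(100.0 / 5)

    def test_fixed_seed_identical_tables(self):
        pool = make_genotype_pool(seed=0)
        t1, _ = generate_marker_dataset(20, pool, seed=5)
        t2, _ = generate_marker_dataset(20, pool, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            generate_marker_dataset(5, [], seed=0)


class TestFastaIO:
    def test_round_trip_preserves_topology(self, scenario, tmp_path):
        path = tmp_path / "phage.fa"
        write_fasta([scenario.phage], path)
        back = read_fasta(path)[0]
        assert back.seq == scenario.phage.seq
        assert back.circular
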