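"""Protein identity, genotype clustering, coverage and abundance."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from phagehost._dp import global_identity
from phagehost.markers import (
    MarkerSeq,
    cluster_genotypes,
    coverage_from_alignments,
    filter_alignment_columns,
    occurrence_matrix,
    pairwise_identity,
    relative_abundance,
)
from phagehost.simulate.markers import generate_marker_dataset, make_genotype_pool

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")
NEG = -(10 ** 9)


def oracle_alignment(s1: str, s2: str, gap_open: int = 11, gap_extend: int = 1):
    """Independent affine-gap Needleman-Wunsch (memoized recursion).

    Same scoring contract as the production kernel: BLOSUM62, a gap of
    length k costs open + k * extend, ties broken substitution > gap-in-b >
    gap-in-a. Returns (identity, score).
    """
    n, m = len(s1), len(s2)
    oc = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def state(i, j, k):
        if i == 0 and j == 0:
            return 0 if k == 0 else NEG
        if k == 0:  # substitution ending at (i, j)
            if i == 0 or j == 0:
                return NEG
            prev = max(state(i - 1, j - 1, 0), state(i - 1, j - 1, 1),
                       state(i - 1, j - 1, 2))
            return prev + _B62[s1[i - 1], s2[j - 1]]
        if k == 1:  # gap in s2 (consumes s1[i-1])
            if i == 0:
                return NEG
            return max(state(i - 1, j, 0) - oc, state(i - 1, j, 1) - gap_extend)
        if j == 0:
            return NEG
        return max(state(i, j - 1, 0) - oc, state(i, j - 1, 2) - gap_extend)

    scores = [state(n, m, k) for k in range(3)]
    best = max(scores)
    k = scores.index(best)  # preference M > Ix > Iy on ties
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        columns += 1
        if k == 0:
            if s1[i - 1] == s2[j - 1]:
                matches += 1
            prev = state(i, j, 0) - _B62[s1[i - 1], s2[j - 1]]
            for kk in range(3):
                if state(i - 1, j - 1, kk) == prev:
                    k = kk
                    break
            i, j = i - 1, j - 1
        elif k == 1:
            k = 0 if state(i - 1, j, 0) - oc == state(i, j, 1) else 1
            i -= 1
        else:
            k = 0 if state(i, j - 1, 0) - oc == state(i, j, 2) else 2
            j -= 1
    return matches / columns, best


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVLA", "MKVLA") == 1.0

    def test_three_of_four_columns(self):
        assert pairwise_identity("AAAA", "AAAT") == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(4, 31, size=2)
        s1 = "".join(AA[i] for i in rng.integers(0, 20, n1))
        s2 = "".join(AA[i] for i in rng.integers(0, 20, n2))
        ident, score = global_identity(s1, s2)
        o_ident, o_score = oracle_alignment(s1, s2)
        assert score == o_score
        assert ident == pytest.approx(o_ident)

    def test_optimal_score_matches_biopython(self):
        from Bio import Align

        al = Align.PairwiseAligner()
        al.substitution_matrix = _B62
        al.mode = "global"
        al.open_gap_score = -12
        al.extend_gap_score = -1
        rng = np.random.default_rng(99)
        for _ in range(10):
            n1, n2 = rng.integers(5, 40, size=2)
            s1 = "".join(AA[i] for i in rng.integers(0, 20, n1))
            s2 = "".join(AA[i] for i in rng.integers(0, 20, n2))
            assert global_identity(s1, s2)[1] == al.align(s1, s2).score


def _marker(i, sample, prot):
    return MarkerSeq(f"m{i}", sample, "rpS3", prot)


class TestGenotypeClustering:
    def test_identical_sequences_form_one_genotype(self):
        ms = [_marker(i, f"s{i}", "MKVLATRE" * 10) for i in range(5)]
        table = cluster_genotypes(ms, threshold=0.99)
        assert len(table.members) == 1
        assert len(next(iter(table.members.values()))) == 5

    def test_98_percent_pair_splits_at_99_threshold(self):
        base = "MKVLATREPQWHISDF" * 10  # 160 aa
        variant = "AA" + base[2:]  # 2 substitutions -> 98.75%... make 4
        variant = "AAAA" + base[4:]  # 4 subs over 160 = 97.5%
        assert pairwise_identity(base, variant) < 0.99
        table = cluster_genotypes([_marker(0, "s", base),
                                   _marker(1, "s", variant)], 0.99)
        assert len(table.members) == 2
        # same pair clusters together at the 80% grouping threshold
        table80 = cluster_genotypes([_marker(0, "s", base),
                                     _marker(1, "s", variant)], 0.80)
        assert len(table80.members) == 1

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.text(alphabet="MKVLA", min_size=3, max_size=12),
                    min_size=1, max_size=8))
    def test_threshold_one_equals_exact_dedup(self, prots):
        ms = [_marker(i, "s", p) for i, p in enumerate(prots)]
        table = cluster_genotypes(ms, threshold=1.0)
        assert len(table.members) == len(set(prots))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            cluster_genotypes([], threshold=0.0)


class TestOccurrence:
    def test_single_observation(self):
        table = cluster_genotypes([_marker(0, "s0", "MKVLA" * 10)], 0.99)
        mat = occurrence_matrix(table)
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == 1

    def test_matches_planted_presence(self):
        pool = make_genotype_pool(n_target=3, n_other=2, n_phage=2, seed=4)
        table, truth = generate_marker_dataset(25, pool, seed=4)
        ms = [MarkerSeq(f"{r.genotype_id}|{r.sample}", r.sample, r.marker,
                        r.protein) for r in table.itertuples()]
        gt = cluster_genotypes(ms, threshold=0.99)
        mat = occurrence_matrix(gt)
        # same number of detections per sample as planted
        planted_per_sample = truth.presence.sum(axis=0)
        for s in mat.columns:
            assert mat[s].sum() == planted_per_sample[s]

    def test_sample_and_sequence_order_invariance(self):
        rng = np.random.default_rng(0)
        prots = ["MKVLATRE" * 8, "WWHHIIPP" * 8, "DDEEFFGG" * 8]
        ms = [_marker(i, f"s{i % 3}", prots[i % 3]) for i in range(9)]
        m1 = occurrence_matrix(cluster_genotypes(ms, 0.99))
        shuffled = [ms[i] for i in rng.permutation(len(ms))]
        m2 = occurrence_matrix(cluster_genotypes(shuffled, 0.99))
        assert m1.sort_index().equals(m2.sort_index())


class TestCoverage:
    def _aln(self, n_reads, nm, m_len=150, ref="gene"):
        return pd.DataFrame({
            "read_id": range(n_reads), "ref": ref, "nm": nm, "m_len": m_len,
        })

    def test_ten_clean_reads_give_unit_coverage(self):
        cov = coverage_from_alignments(self._aln(10, 0), {"gene": 1500})
        assert cov["gene"] == pytest.approx(1.0)

    def test_mismatch_filter_drops_everything(self):
        cov = coverage_from_alignments(self._aln(10, 4), {"gene": 1500})
        assert cov["gene"] == 0.0

    def test_missing_nm_is_an_error(self):
        aln = self._aln(3, 0)
        aln.loc[1, "nm"] = np.nan
        with pytest.raises(ValueError, match="mismatch"):
            coverage_from_alignments(aln, {"gene": 1500})

    def test_monotone_in_max_mismatch(self):
        rng = np.random.default_rng(1)
        aln = self._aln(200, rng.integers(0, 6, 200))
        lengths = {"gene": 1500}
        prev = -1.0
        for mm in range(6):
            cov = coverage_from_alignments(aln, lengths, max_mismatch=mm)
            assert cov["gene"] >= prev
            prev = cov["gene"]

    def test_poisson_depth_recovery(self):
        # planted depth d; estimate within 3 SD of the Poisson count model
        from phagehost.simulate.markers import sample_marker_alignments

        d, L, R = 20.0, 1500, 150
        lengths = pd.Series({"gene": float(L)})
        aln = sample_marker_alignments(pd.Series({"gene": d}), lengths,
                                       read_length=R,
                                       rng=np.random.default_rng(8))
        cov = coverage_from_alignments(aln, lengths)
        sd = np.sqrt(d * L / R) * R / L
        assert abs(cov["gene"] - d) < 3 * sd


class TestRelativeAbundance:
    def test_target_equals_total_gives_100(self):
        res = relative_abundance({"a": 5.0, "b": 3.0}, ["a", "b"], [])
        assert res.taxon_pct == pytest.approx(100.0)

    def test_simple_ratio(self):
        cov = {"t": 10.0, "o1": 40.0, "o2": 50.0, "ph": 7.0}
        res = relative_abundance(cov, ["t"], ["ph"])
        assert res.taxon_pct == pytest.approx(10.0)
        assert res.phage_pct == pytest.approx(7.0)
        assert res.b == pytest.approx(100.0)

    def test_partition_sums_to_100(self):
        cov = {f"g{i}": float(i + 1) for i in range(6)}
        t1 = relative_abundance(cov, ["g0", "g1"], [])
        t2 = relative_abundance(cov, ["g2", "g3", "g4", "g5"], [])
        assert t1.taxon_pct + t2.taxon_pct == pytest.approx(100.0)

    def test_zero_denominator_flagged(self):
        res = relative_abundance({"ph": 5.0}, [], ["ph"])
        assert res.undefined and res.taxon_pct is None

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance({"a": 1.0}, ["zzz"], [])


class TestColumnFilter:
    def test_all_gap_column_removed(self):
        msa = ["A-C", "A-C", "A-C"]
        rows, kept = filter_alignment_columns(msa, trim_termini=False)
        assert rows == ["AC", "AC", "AC"]
        assert list(kept) == [0, 2]

    def test_exact_boundary_gap_fraction_retained(self):
        # 19 of 20 gaps = 0.95: kept (strict >); 20 of 20 removed
        col95 = ["-"] * 19 + ["A"]
        col100 = ["-"] * 20
        msa = ["".join(p) for p in zip("A" * 20, col95, col100, "C" * 20)]
        rows, kept = filter_alignment_columns(msa, trim_termini=False)
        assert list(kept) == [0, 1, 3]

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        msa = ["".join(rng.choice(list("ACDEF-"), 40)) for _ in range(12)]
        rows, kept = filter_alignment_columns(msa, max_gap_fraction=0.4,
                                              trim_termini=False)
        expected = [j for j in range(40)
                    if sum(r[j] == "-" for r in msa) / 12 <= 0.4]
        assert list(kept) == expected

    def test_terminal_trim(self):
        msa = ["--AC--", "-AACA-", "AAACAA"]
        rows, kept = filter_alignment_columns(msa, terminus_gap_fraction=0.4)
        # outermost columns (2/3 gaps) are ambiguous termini; the first and
        # last columns with <= 40% gaps bound the kept block
        assert list(kept) == [1, 2, 3, 4]
        assert rows[2] == "AACA"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            filter_alignment_columns([])
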