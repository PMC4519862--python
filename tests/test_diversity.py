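"""Diversity statistics, distance models and neutrality tests."""

import math
from itertools import permutations

import numpy as np
import pytest

from invabc import diversity
from invabc.diversity import (
    distance_matrix,
    ewens_log_pmf,
    fu_fs_statistic,
    fu_li_Dstar,
    fu_Fs,
    haplotype_diversity,
    log_stirling1,
    nucleotide_diversity,
    pairwise_difference_matrix,
    segregating_sites,
    tajima_D,
)
from invabc.seq_io import PopulationMap, collapse_haplotypes

from conftest import make_alignment, single_population_map

# frozen oracle values (independent exact-fraction evaluation of the
# published formulas on this alignment: S=4, eta=4, eta_s=2, k=1.8)
NEUTRALITY_SEQS = [
    "ACGTACGTACGTAC",
    "ACGTACGTACGTAC",
    "ACGTACGTACGAAC",
    "ACCTACGTACGAAC",
    "ACCTACGTACGAAC",
    "ACGTACTTACGTGC",
]
EXPECTED_TAJIMA_D = 0.1490791330554159
EXPECTED_FU_LI_DSTAR = 0.07132074114631193


class TestHaplotypeDiversity:
    def test_two_equal_haplotypes(self):
        hd, var, sd = haplotype_diversity([2, 2], 4)
        assert hd == pytest.approx(2 / 3, abs=1e-12)
        assert sd == pytest.approx(math.sqrt(var), abs=1e-15)

    def test_single_haplotype_is_zero(self):
        hd, var, sd = haplotype_diversity([5], 5)
        assert hd == 0.0 and var == 0.0 and sd == 0.0

    def test_undefined_below_two_sequences(self):
        assert all(math.isnan(v) for v in haplotype_diversity([1], 1))


class TestNucleotideDiversity:
    def test_three_sequences_enumerated(self):
        # pairwise differences (0, 2, 2) over 10 sites
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAA", "GGAAAAAAAA"])
        pi, k = nucleotide_diversity(aln)
        assert k == pytest.approx(4 / 3, abs=1e-12)
        assert pi == pytest.approx(4 / 30, abs=1e-12)

    def test_identical_sequences(self):
        pi, k = nucleotide_diversity(make_alignment(["ACGT"] * 3))
        assert pi == 0.0 and k == 0.0

    def test_matches_brute_force_with_gaps(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, L = int(rng.integers(2, 8)), int(rng.integers(4, 25))
            mat = rng.choice(list("ACGT-"), size=(n, L), p=[.23]*4+[.08])
            seqs = ["".join(r) for r in mat]
            aln = make_alignment(seqs)
            mask = aln.complete_sites()
            # brute force on complete columns
            tot = 0
            pairs = 0
            for i in range(n):
                for j in range(i + 1, n):
                    tot += sum(
                        a != b
                        for c, (a, b) in enumerate(zip(seqs[i], seqs[j]))
                        if mask[c]
                    )
                    pairs += 1
            k_bf = tot / pairs
            pi_bf = k_bf / mask.sum() if mask.sum() else math.nan
            pi, k = nucleotide_diversity(aln)
            assert k == pytest.approx(k_bf, abs=1e-9)
            if mask.sum():
                assert pi == pytest.approx(pi_bf, abs=1e-9)


class TestDistances:
    def _haps(self, seqs):
        aln = make_alignment(seqs)
        return collapse_haplotypes(aln, single_population_map(aln))

    def test_k2p_closed_form(self):
        # 10 transitions over 100 sites, no transversions
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        d = distance_matrix(self._haps([a, b]), "K2P")
        assert d.entries[0, 1] == pytest.approx(0.11157177565710485, abs=1e-9)

    def test_identical_haplotypes_zero_under_all_models(self):
        for model in ("p", "JC69", "K2P", "MCL"):
            d = distance_matrix(self._haps(["ACGTACGT", "ACGTACGA"]), model)
            assert d.entries[0, 0] == 0.0
            assert d.entries[0, 1] == d.entries[1, 0] >= 0.0

    def test_k2p_matches_jc69_at_expected_ts_tv_mix(self):
        # with transitions:transversions = 1:2 K2P collapses to JC69
        L = 3000
        a = "A" * L
        b = "G" * 10 + "C" * 10 + "T" * 10 + "A" * (L - 30)
        haps = self._haps([a, b])
        k2p = distance_matrix(haps, "K2P").entries[0, 1]
        jc = distance_matrix(haps, "JC69").entries[0, 1]
        assert k2p == pytest.approx(jc, rel=1e-3)

    def test_saturated_pairs_flagged(self):
        a = "A" * 8
        b = "G" * 8
        with pytest.warns(UserWarning, match="saturated"):
            d = distance_matrix(self._haps([a, b]), "JC69")
        assert math.isnan(d.entries[0, 1]) and math.isnan(d.mean)

    def test_mean_recomputable_from_entries(self):
        rng = np.random.default_rng(11)
        mat = rng.choice(list("ACGT"), size=(5, 60))
        d = distance_matrix(self._haps(["".join(r) for r in mat]), "MCL")
        upper = d.entries[np.triu_indices(d.entries.shape[0], 1)]
        assert d.mean == pytest.approx(np.nanmean(upper), abs=1e-12)


class TestNeutralityTests:
    def test_tajima_d_matches_frozen_oracle(self):
        assert tajima_D(make_alignment(NEUTRALITY_SEQS)) == pytest.approx(
            EXPECTED_TAJIMA_D, abs=1e-12
        )

    def test_fu_li_dstar_matches_frozen_oracle(self):
        assert fu_li_Dstar(make_alignment(NEUTRALITY_SEQS)) == pytest.approx(
            EXPECTED_FU_LI_DSTAR, abs=1e-12
        )

    def test_undefined_without_segregating_sites(self):
        aln = make_alignment(["ACGT"] * 5)
        assert math.isnan(tajima_D(aln))
        assert math.isnan(fu_li_Dstar(aln))

    def test_stirling_numbers_satisfy_rising_factorial_identity(self):
        # sum_k |s(n,k)| x^k = x (x+1) ... (x+n-1)
        for n in range(1, 11):
            logs = log_stirling1(n)
            for x in (0.5, 1.0, 2.5):
                lhs = float(np.sum(np.exp(logs[1:]) * x ** np.arange(1, n + 1)))
                rhs = float(np.prod(x + np.arange(n)))
                assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_ewens_pmf_normalizes(self):
        for n, theta in [(5, 0.5), (8, 2.0), (40, 5.0)]:
            logp = ewens_log_pmf(n, theta)
            assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-10)

    def test_fs_undefined_when_all_allele_counts_certain(self):
        # K >= 1 always, so S' = 1 and Fs is a log of infinity
        assert math.isnan(fu_fs_statistic(6, 1, 1.0))

    def test_fu_fs_positive_for_deficit_of_alleles(self):
        # few haplotypes given theta -> S' large -> Fs positive
        fs = fu_fs_statistic(20, 2, 5.0)
        assert fs > 0

    def test_fu_fs_pvalue_from_null_simulation(self):
        aln = make_alignment(NEUTRALITY_SEQS)
        fs, p = fu_Fs(aln, n_null_sims=200, seed=0)
        assert not math.isnan(fs)
        assert 0.0 <= p <= 1.0

    def test_fu_fs_undefined_without_diversity(self):
        fs, p = fu_Fs(make_alignment(["ACGT"] * 4))
        assert math.isnan(fs) and math.isnan(p)


class TestReports:
    def test_population_report_shape(self):
        aln = make_alignment(NEUTRALITY_SEQS)
        popmap = PopulationMap(
            {f"s{i}": ("P1" if i < 3 else "P2") for i in range(6)}
        )
        rep = diversity.population_report(aln, popmap, n_null_sims=50, seed=0)
        assert list(rep["population"]) == ["P1", "P2", "overall"]
        overall = rep[rep["population"] == "overall"].iloc[0]
        assert overall["n"] == 6
        assert overall["S"] == segregating_sites(aln)

    def test_pairwise_matrix_symmetry(self):
        aln = make_alignment(NEUTRALITY_SEQS)
        d = pairwise_difference_matrix(aln)
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
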