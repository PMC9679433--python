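import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import haplostock as hs
from haplostock.errors import SinglePopulationError, TooFewSamplesError
from _oracles import (
    gene_diversity_pairs,
    hamming_pairwise_deletion,
    nucleotide_diversity_loops,
)
from conftest import random_seqset


class TestCollapse:
    def test_exact_match_collapse(self):
        seqs = hs.AlignedSeqSet.from_strings(
            ["a", "b", "c", "d"], ["AAA", "AAA", "AAT", "ACT"])
        table = hs.collapse(seqs)
        assert table.n_haplotypes == 3
        assert sorted(table.counts) == [1, 1, 2]
        assert table.n == 4

    def test_identical_sequences_single_haplotype(self):
        seqs = hs.AlignedSeqSet.from_strings(
            [f"s{i}" for i in range(10)], ["ACGT"] * 10)
        table = hs.collapse(seqs)
        assert table.n_haplotypes == 1
        assert table.counts[0] == 10

    def test_members_partition_sample_set(self, tiny_dataset):
        for table in hs.collapse_haplotypes(tiny_dataset, "site"):
            members = [m for ms in table.members for m in ms]
            assert len(members) == len(set(members)) == table.n
            assert len(set(table.haplotypes)) == table.n_haplotypes

    def test_unknown_group_key(self, tiny_dataset):
        from haplostock.errors import UnknownGroupKeyError

        with pytest.raises(UnknownGroupKeyError):
            hs.collapse_haplotypes(tiny_dataset, "nonexistent")


class TestDistances:
    @pytest.mark.parametrize("s1,s2,d,comp", [
        ("ACGT", "ACGA", 1, 4),
        ("AC-T", "ACGT", 0, 3),   # gap column dropped pairwise
        ("ANGT", "ACGT", 0, 3),   # N treated as missing
        ("ACGT", "ACGT", 0, 4),
        ("NNNN", "ACGT", 0, 0),
    ])
    def test_pairwise_deletion_rules(self, s1, s2, d, comp):
        seqs = hs.AlignedSeqSet.from_strings(["x", "y"], [s1, s2])
        dm = hs.pairwise_distances(seqs)
        assert dm.d[0, 1] == d
        assert dm.comparable[0, 1] == comp

    def test_matrix_invariants(self, rng):
        seqs = random_seqset(rng, 15, 30, alphabet="ACGTN-")
        dm = hs.pairwise_distances(seqs)
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all(dm.d <= dm.comparable)

    def test_matches_bruteforce(self, rng):
        seqs = random_seqset(rng, 8, 25, alphabet="ACGTN-")
        dm = hs.pairwise_distances(seqs)
        for i in range(8):
            for j in range(i + 1, 8):
                d, comp = hamming_pairwise_deletion(seqs.sequence(i), seqs.sequence(j))
                assert dm.d[i, j] == d and dm.comparable[i, j] == comp

    def test_complete_deletion_drops_columns_globally(self):
        seqs = hs.AlignedSeqSet.from_strings(
            ["x", "y", "z"], ["ACGT", "ACNT", "TCGT"])
        dm = hs.pairwise_distances(seqs, mode="complete-deletion")
        # column 3 (N in y) dropped for everyone
        assert np.all(dm.comparable == 3)
        assert dm.d[0, 2] == 1


class TestHaplotypeDiversity:
    def test_hand_computed_example(self):
        table = hs.HaplotypeTable(
            label="x", haplotypes=["AAA", "AAT", "ACT"],
            members=[["a", "b"], ["c"], ["d"]])
        # (4/3) * (1 - (1/4 + 1/16 + 1/16)) = 5/6
        assert hs.haplotype_diversity(table) == pytest.approx(5 / 6)
        assert hs.haplotype_diversity(table) == pytest.approx(
            gene_diversity_pairs([2, 1, 1]))

    def test_all_unique_gives_one(self):
        for n in range(2, 9):
            table = hs.HaplotypeTable(
                label="x", haplotypes=[f"h{i}" for i in range(n)],
                members=[[f"s{i}"] for i in range(n)])
            assert hs.haplotype_diversity(table) == pytest.approx(1.0)

    def test_monomorphic_gives_zero(self):
        table = hs.HaplotypeTable(label="x", haplotypes=["AAA"],
                                  members=[["a", "b", "c"]])
        assert hs.haplotype_diversity(table) == 0.0

    def test_single_sample_rejected(self):
        table = hs.HaplotypeTable(label="x", haplotypes=["A"], members=[["a"]])
        with pytest.raises(TooFewSamplesError):
            hs.haplotype_diversity(table)

    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=2, max_size=6))
    def test_agrees_with_pair_fraction_oracle(self, counts):
        if sum(counts) < 2:
            counts = counts + [1]
        table = hs.HaplotypeTable(
            label="x", haplotypes=[f"h{i}" for i in range(len(counts))],
            members=[[f"s{i}_{j}" for j in range(c)] for i, c in enumerate(counts)])
        assert hs.haplotype_diversity(table) == pytest.approx(
            gene_diversity_pairs(counts))


class TestNucleotideDiversity:
    def test_two_sequences_one_difference(self):
        seqs = hs.AlignedSeqSet.from_strings(["a", "b"],
                                             ["ACGTACGTAC", "ACGTACGTAT"])
        assert hs.nucleotide_diversity(hs.pairwise_distances(seqs)) == pytest.approx(0.10)

    def test_identical_sequences_zero(self):
        seqs = hs.AlignedSeqSet.from_strings(["a", "b", "c"], ["ACGT"] * 3)
        assert hs.nucleotide_diversity(hs.pairwise_distances(seqs)) == 0.0

    def test_mean_over_pairs(self):
        # per-site pairwise distances {0.1, 0.2, 0.3, 0.1, 0.2, 0.1}: mean 1/6
        seqs = hs.AlignedSeqSet.from_strings(
            ["a", "b", "c", "d"],
            ["AAAAAAAAAA", "TAAAAAAAAA", "TTAAAAAAAA", "TTTAAAAAAA"])
        assert hs.nucleotide_diversity(hs.pairwise_distances(seqs)) == pytest.approx(
            (0.1 + 0.2 + 0.3 + 0.1 + 0.2 + 0.1) / 6)

    def test_agrees_with_double_loop(self, rng):
        seqs = random_seqset(rng, 12, 40, alphabet="ACGTN")
        dm = hs.pairwise_distances(seqs)
        assert hs.nucleotide_diversity(dm) == pytest.approx(
            nucleotide_diversity_loops(seqs.sequences()))

    def test_no_comparable_pair_rejected(self):
        from haplostock.errors import NoComparablePairsError

        seqs = hs.AlignedSeqSet.from_strings(["a", "b"], ["ANNN", "NAAA"])
        with pytest.raises(NoComparablePairsError):
            hs.nucleotide_diversity(hs.pairwise_distances(seqs))


class TestSiteAlleleStats:
    def _dataset(self, pops):
        import pandas as pd

        ids, seqs, sites = [], [], []
        for pop, seq_list in pops.items():
            for i, s in enumerate(seq_list):
                ids.append(f"{pop}{i}")
                seqs.append(s)
                sites.append(pop)
        aln = hs.AlignedSeqSet.from_strings(ids, seqs)
        df = pd.DataFrame({
            "site": sites, "collection_date": pd.Timestamp("2014-01-01"),
            "role": "estuary", "site_treatment": "reference",
            "stocking_epoch": "pre",
        }, index=pd.Index(ids, name="sample_id"))
        return hs.bind(aln, hs.SampleFrame(df))

    def test_private_allele_enumeration(self):
        data = self._dataset({"p1": ["AA", "AT"], "p2": ["AA", "AA"]})
        stats = hs.site_allele_stats(data)
        assert stats["p1"]["n_polymorphic_sites"] == 1
        assert stats["p2"]["n_polymorphic_sites"] == 0
        # T at position 2 occurs only in p1
        assert stats["p1"]["n_private_alleles"] == 1
        assert stats["p2"]["n_private_alleles"] == 0
        assert stats["p1"]["mean_n_alleles_per_site"] == pytest.approx(1.5)

    def test_identical_populations_no_private_alleles(self):
        data = self._dataset({"p1": ["ACGT", "AGGT"], "p2": ["ACGT", "AGGT"]})
        stats = hs.site_allele_stats(data)
        assert all(s["n_private_alleles"] == 0 for s in stats.values())

    def test_single_population_rejected(self):
        data = self._dataset({"p1": ["AA", "AT"]})
        with pytest.raises(SinglePopulationError):
            hs.site_allele_stats(data)


class TestDivergenceMatrix:
    def _dataset(self, pops):
        return TestSiteAlleleStats._dataset(self, pops)

    def test_fixed_populations(self):
        a = "A" * 100
        b = "A" * 98 + "TT"
        data = self._dataset({"p1": [a, a], "p2": [b, b]})
        div = hs.divergence_matrix(data)
        assert div.loc["p1", "p1"] == 0.0
        assert div.loc["p2", "p2"] == 0.0
        assert div.loc["p1", "p2"] == pytest.approx(2.0)

    def test_duplicated_population_between_tracks_within(self, rng):
        """A population split into two identical copies: the between mean
        equals the within mean up to the (n-1)/n factor from the n zero
        distances between each sequence and its own copy."""
        n = 6
        seqs = random_seqset(rng, n, 30)
        strs = seqs.sequences()
        data = self._dataset({"p1": strs, "p2": strs})
        div = hs.divergence_matrix(data)
        assert div.loc["p1", "p2"] == pytest.approx(
            div.loc["p1", "p1"] * (n - 1) / n)
        assert div.loc["p1", "p2"] == pytest.approx(div.loc["p2", "p1"])

    def test_label_swap_invariance(self, rng):
        seqs = random_seqset(rng, 8, 30)
        strs = seqs.sequences()
        d1 = hs.divergence_matrix(self._dataset({"A": strs[:4], "B": strs[4:]}))
        d2 = hs.divergence_matrix(self._dataset({"B": strs[:4], "A": strs[4:]}))
        assert d1.loc["A", "B"] == pytest.approx(d2.loc["B", "A"])
        # after the swap, the first half's within-divergence lives under "B"
        assert d1.loc["A", "A"] == pytest.approx(d2.loc["B", "B"])


class TestCompareSiteCounts:
    def _summaries(self, counts, allele_arrays=None):
        out = []
        for i, c in enumerate(counts):
            out.append(hs.DiversitySummary(
                label=f"g{i}", n=10, n_haplotypes=c, h=1.0, pi=0.02,
                n_polymorphic_sites=c, n_private_alleles=c,
                mean_n_alleles_per_site=1.0,
                per_site_allele_counts=(
                    None if allele_arrays is None else allele_arrays[i]),
            ))
        return out

    def test_equal_counts_statistic_zero(self):
        report = hs.compare_site_counts(self._summaries([50, 50, 50]))
        comp = report.comparisons["n_haplotypes"]
        assert comp.statistic == pytest.approx(0.0)
        assert comp.p_value == pytest.approx(1.0)
        # everything shares one homogeneous-group letter
        assert len(set(comp.letters.values())) == 1

    def test_chi_square_hand_value(self):
        report = hs.compare_site_counts(self._summaries([10, 0]))
        comp = report.comparisons["n_haplotypes"]
        # sum (O-E)^2/E with E=5: 25/5 + 25/5 = 10 on 1 dof
        assert comp.statistic == pytest.approx(10.0)
        assert comp.df == 1

    def test_identical_allele_counts_anova_f_zero(self):
        arrays = [np.full(20, 2.0) for _ in range(3)]
        report = hs.compare_site_counts(self._summaries([5, 5, 5], arrays))
        comp = report.comparisons["mean_n_alleles_per_site"]
        assert comp.statistic == 0.0
        assert comp.p_value == 1.0

    def test_degenerate_counts_rejected(self):
        from haplostock.errors import DegenerateCountsError

        with pytest.raises(DegenerateCountsError):
            hs.compare_site_counts(self._summaries([0, 0]))

    def test_divergent_group_gets_own_letter(self, rng):
        arrays = [rng.normal(2.0, 0.05, 50), rng.normal(2.0, 0.05, 50),
                  rng.normal(3.5, 0.05, 50)]
        report = hs.compare_site_counts(self._summaries([5, 5, 5], arrays))
        letters = report.comparisons["mean_n_alleles_per_site"].letters
        assert letters["g0"] == letters["g1"]
        assert letters["g2"] != letters["g0"]


def test_all_unique_input_gives_h_one_after_collapse(rng):
    """collapse then haplotype_diversity on all-unique input gives h = 1."""
    for n in [2, 5, 17]:
        seqs = random_seqset(rng, n, 60)
        table = hs.collapse(seqs)
        if table.n_haplotypes == n:  # random 60-mers: collisions essentially never
            assert hs.haplotype_diversity(table) == pytest.approx(1.0)
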