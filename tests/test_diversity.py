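"""Diversity/differentiation estimators against hand computations and
closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylocorridor import (
    ConfigurationError,
    DistanceMatrix,
    GeneticSimConfig,
    HaplotypeDataset,
    InputError,
    SSRGenotypes,
    allelic_richness,
    hamming_distances,
    haplotype_diversity,
    heterozygosity_and_fis,
    make_haplotype_chain,
    multilocus_gst,
    nst_gst_test,
    simulate_ssr,
    uniform_distances,
)
from phylocorridor.datatypes import MISSING_ALLELE


def make_genotypes(rows, loci):
    """rows: list of (pop, [(a1, b1), (a2, b2), ...]) tuples."""
    pop_ids = [r[0] for r in rows]
    individual_ids = [f"I{i}" for i in range(len(rows))]
    alleles = np.array([r[1] for r in rows])
    return SSRGenotypes(
        pop_ids=pop_ids, individual_ids=individual_ids,
        locus_names=loci, alleles=alleles,
    )


class TestHammingDistances:
    def test_examples(self):
        ds = HaplotypeDataset(
            haplotype_ids=["A", "B", "C"],
            sequences={"A": "ACGT", "B": "ACGT", "C": "ACGA"},
            counts=[[1, 1, 1]],
            pop_ids=["p"],
        )
        d = hamming_distances(ds)
        assert d.d[0, 1] == 0
        assert d.d[0, 2] == 1

    def test_chain_matrix(self):
        ds = make_haplotype_chain(4, 10, seed=3)
        d = hamming_distances(ds).d
        expected = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        np.testing.assert_array_equal(d, expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            HaplotypeDataset(
                haplotype_ids=["A", "B"],
                sequences={"A": "ACGT", "B": "ACG"},
                counts=[[1, 1]],
                pop_ids=["p"],
            )


class TestHaplotypeDiversity:
    def test_monomorphic_everywhere(self):
        ds = HaplotypeDataset(
            haplotype_ids=["H1"], sequences={"H1": "ACGT"},
            counts=[[5], [7]], pop_ids=["P1", "P2"],
        )
        res = haplotype_diversity(ds)
        assert res.hS == 0.0
        assert res.hT == pytest.approx(0.0, abs=1e-12)
        assert res.GST is None
        assert res.flags

    def test_two_fixed_populations_hand_computed(self, two_fixed_pops):
        # h_k = 0; xbar = (1/2, 1/2); n_tilde = 5, s = 2
        # hT = 1 - 1/2 + 0 = 1/2; GST = (0.5 - 0)/0.5 = 1
        res = haplotype_diversity(two_fixed_pops, uniform_distances(two_fixed_pops))
        assert res.hS == 0.0
        assert res.hT == pytest.approx(0.5)
        assert res.GST == pytest.approx(1.0)
        assert res.NST == pytest.approx(1.0)

    def test_uniform_distances_make_nst_equal_gst(self, panmictic_dataset):
        res = haplotype_diversity(panmictic_dataset, uniform_distances(panmictic_dataset))
        assert abs(res.NST - res.GST) < 1e-12

    def test_scaled_uniform_distances_also_collapse(self, panmictic_dataset):
        n = panmictic_dataset.n_haplotypes
        d = DistanceMatrix(
            labels=list(panmictic_dataset.haplotype_ids),
            d=3.7 * (np.ones((n, n)) - np.eye(n)),
        )
        res = haplotype_diversity(panmictic_dataset, d)
        assert abs(res.NST - res.GST) < 1e-12

    def test_singleton_population_excluded_with_warning(self):
        ds = HaplotypeDataset(
            haplotype_ids=["H1", "H2"],
            sequences={"H1": "AAAA", "H2": "AAAT"},
            counts=[[3, 2], [1, 0]],
            pop_ids=["big", "single"],
        )
        with pytest.warns(UserWarning, match="single"):
            res = haplotype_diversity(ds)
        assert res.excluded_pops == ["single"]
        assert np.isnan(res.h_k["single"])

    def test_pooled_self_consistency(self, panmictic_dataset):
        res = haplotype_diversity(panmictic_dataset.pooled())
        assert res.hS == pytest.approx(res.hT, abs=1e-12)

    def test_relabeling_invariance(self, panmictic_dataset):
        ds = panmictic_dataset
        d = hamming_distances(ds)
        res = haplotype_diversity(ds, d)
        perm = np.random.default_rng(0).permutation(ds.n_haplotypes)
        ids = [ds.haplotype_ids[i] for i in perm]
        shuffled = HaplotypeDataset(
            haplotype_ids=ids,
            sequences=ds.sequences,
            counts=ds.counts[:, perm],
            pop_ids=ds.pop_ids,
        )
        res2 = haplotype_diversity(shuffled, hamming_distances(shuffled))
        assert res2.hS == pytest.approx(res.hS)
        assert res2.hT == pytest.approx(res.hT)
        assert res2.NST == pytest.approx(res.NST)


class TestStructureTest:
    def test_uniform_distance_matrix_gives_p_one(self, panmictic_dataset):
        res = nst_gst_test(
            panmictic_dataset, uniform_distances(panmictic_dataset),
            n_perm=99, seed=0,
        )
        assert res.p_value == 1.0

    def test_too_few_permutations_rejected(self, panmictic_dataset, chain8):
        with pytest.raises(ConfigurationError):
            nst_gst_test(panmictic_dataset, hamming_distances(chain8), n_perm=50)

    def test_detects_planted_ordered_structure(self, structured_dataset):
        ds, chain = structured_dataset
        res = nst_gst_test(ds, hamming_distances(chain), n_perm=999, seed=1)
        assert res.NST_obs > res.GST_obs
        assert res.p_value <= 0.05
        assert res.U > 0

    def test_p_value_bounds(self, structured_dataset):
        ds, chain = structured_dataset
        res = nst_gst_test(ds, hamming_distances(chain), n_perm=199, seed=5)
        assert 1 / 200 <= res.p_value <= 1.0


class TestAllelicRichness:
    def test_full_sample_equals_allele_count(self):
        geno = make_genotypes(
            [("P1", [(100, 102)]), ("P1", [(100, 104)]), ("P1", [(104, 104)])],
            ["L1"],
        )
        per_pop, per_locus, g = allelic_richness(geno, g=6)
        assert g == 6
        assert per_pop["P1"] == pytest.approx(3.0)

    def test_nine_one_at_g_two(self):
        # N = 10 copies, counts (9, 1): AR(2) = 2 - C(9,2)/C(10,2) = 1.2
        rows = [("P1", [(100, 100)])] * 4 + [("P1", [(100, 102)])]
        geno = make_genotypes(rows, ["L1"])
        per_pop, _, _ = allelic_richness(geno, g=2)
        assert per_pop["P1"] == pytest.approx(1.2)

    def test_monomorphic_locus_is_one_for_all_g(self):
        rows = [("P1", [(100, 100)])] * 5
        geno = make_genotypes(rows, ["L1"])
        for g in range(1, 11):
            per_pop, _, _ = allelic_richness(geno, g=g)
            assert per_pop["P1"] == pytest.approx(1.0)

    @given(
        counts=st.lists(st.integers(1, 6), min_size=1, max_size=4).filter(
            lambda c: 2 <= sum(c) <= 12
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_g_and_exact_at_full_sample(self, counts):
        # one population, one locus with the given allele copy counts
        total = sum(counts)
        copies = [a for i, c in enumerate(counts) for a in [100 + 2 * i] * c]
        if total % 2:
            copies.append(copies[-1])
            total += 1
        rows = [("P1", [(copies[2 * i], copies[2 * i + 1])]) for i in range(total // 2)]
        geno = make_genotypes(rows, ["L1"])
        values = [allelic_richness(geno, g=g)[0]["P1"] for g in range(1, total + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        observed_alleles = len(set(copies))
        assert values[-1] == pytest.approx(observed_alleles)

    def test_invalid_g_rejected(self):
        geno = make_genotypes([("P1", [(100, 102)])], ["L1"])
        with pytest.raises(ConfigurationError):
            allelic_richness(geno, g=0)
        with pytest.raises(ConfigurationError):
            allelic_richness(geno, g=10)


class TestHeterozygosity:
    def test_all_homozygous_fis_one(self):
        rows = [("P1", [(100, 100)])] * 5 + [("P1", [(102, 102)])] * 5
        geno = make_genotypes(rows, ["L1"])
        res = heterozygosity_and_fis(geno)
        row = res.table.loc["P1"]
        assert row["HO"] == 0.0
        assert row["HE"] > 0
        assert row["FIS"] == pytest.approx(1.0)

    def test_single_heterozygote_unbiased_he(self):
        geno = make_genotypes([("P1", [(100, 102)])], ["L1"])
        res = heterozygosity_and_fis(geno, g=2)
        row = res.table.loc["P1"]
        assert row["HO"] == 1.0
        # 2n/(2n-1) * (1 - 0.5) with n = 1 -> 1.0
        assert row["HE"] == pytest.approx(1.0)

    def test_fis_parameter_recovery(self):
        cfg = GeneticSimConfig(
            n_pops=1, n_ind_per_pop=10_000, ssr_n_loci=2,
            ssr_alleles_per_locus=4, inbreeding_f=0.3, seed=13,
        )
        geno = simulate_ssr(cfg)
        res = heterozygosity_and_fis(geno)
        assert res.table.loc["P1", "FIS"] == pytest.approx(0.3, abs=0.02)

    def test_missing_population_flagged_absent(self):
        rows = [
            ("P1", [(100, 102)]),
            ("P2", [(MISSING_ALLELE, MISSING_ALLELE)]),
            ("P2", [(MISSING_ALLELE, MISSING_ALLELE)]),
        ]
        geno = make_genotypes(rows, ["L1"])
        with pytest.warns(UserWarning, match="GST undefined"):
            res = heterozygosity_and_fis(geno, g=2)
        assert np.isnan(res.table.loc["P2", "HE"])
        assert np.isnan(res.table.loc["P2", "AR"])

    def test_nei_variant_matches_ratio(self):
        cfg = GeneticSimConfig(n_pops=2, n_ind_per_pop=100, ssr_n_loci=3, seed=3)
        geno = simulate_ssr(cfg)
        res = heterozygosity_and_fis(geno, fis_estimator="nei")
        for pop in ("P1", "P2"):
            row = res.table.loc[pop]
            assert row["FIS"] == pytest.approx(1 - row["HO"] / row["HE"])


class TestMultilocusGst:
    def test_complete_differentiation(self):
        rows = [("P1", [(100, 100), (200, 200)])] * 5 + [
            ("P2", [(110, 110), (210, 210)])
        ] * 5
        geno = make_genotypes(rows, ["L1", "L2"])
        assert multilocus_gst(geno) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        cfg = GeneticSimConfig(
            n_pops=4, n_ind_per_pop=2000, ssr_n_loci=3, ssr_alleles_per_locus=5, seed=17
        )
        geno = simulate_ssr(cfg)
        assert abs(multilocus_gst(geno)) < 0.01

    def test_toy_table_matches_independent_computation(self):
        rows = [
            ("P1", [(100, 100), (200, 202)]),
            ("P1", [(100, 102), (200, 200)]),
            ("P2", [(102, 102), (202, 202)]),
            ("P2", [(100, 102), (200, 202)]),
            ("P3", [(104, 104), (202, 202)]),
            ("P3", [(102, 104), (202, 202)]),
        ]
        geno = make_genotypes(rows, ["L1", "L2"])

        # independent plain-loop computation of corrected HS/HT per locus
        def locus_stats(locus):
            pop_freqs, ns = [], []
            for pop in ("P1", "P2", "P3"):
                calls = [
                    a
                    for (p, loci) in rows
                    for a in loci[locus]
                    if p == pop
                ]
                alleles = sorted(set(a for (_, loci) in rows for a in loci[locus]))
                n = len(calls) // 2
                freq = [calls.count(a) / len(calls) for a in alleles]
                pop_freqs.append(freq)
                ns.append(n)
            s = len(ns)
            n_tilde = s / sum(1.0 / n for n in ns)
            hs = sum(
                2 * n / (2 * n - 1) * (1 - sum(f * f for f in freq))
                for n, freq in zip(ns, pop_freqs)
            ) / s
            xbar = [sum(f[i] for f in pop_freqs) / s for i in range(len(pop_freqs[0]))]
            ht = 1 - sum(x * x for x in xbar) + hs / (2 * n_tilde * s)
            return hs, ht

        hs1, ht1 = locus_stats(0)
        hs2, ht2 = locus_stats(1)
        expected = ((ht1 + ht2) / 2 - (hs1 + hs2) / 2) / ((ht1 + ht2) / 2)
        assert multilocus_gst(geno) == pytest.approx(expected)

    def test_monomorphic_undefined(self):
        rows = [("P1", [(100, 100)])] * 3 + [("P2", [(100, 100)])] * 3
        geno = make_genotypes(rows, ["L1"])
        assert multilocus_gst(geno) is None
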