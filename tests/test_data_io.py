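"""Formats, preprocessing filters, age binning, pooling and LD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bnsnp import (GenotypeMatrix, PhenotypeTable, SimConfig, bin_age_quartiles,
                   filter_monomorphic, ld_pairwise, pool_datasets,
                   read_genotypes, read_phenotypes, simulate_genotypes,
                   write_genotypes, write_phenotypes)


def _matrix(rows, snp_ids=None, causal=None):
    rows = np.asarray(rows)
    snp_ids = snp_ids or [f"s{j}" for j in range(rows.shape[1])]
    return GenotypeMatrix([f"i{i}" for i in range(rows.shape[0])],
                          list(snp_ids), rows, causal)


class TestGenotypeIO:
    def test_tsv_round_trip_small_fixture(self, tmp_path):
        g = _matrix([[0, 2], [1, 0], [2, 1]], snp_ids=["rsA", "rsB"])
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path)
        assert back.snp_ids == ["rsA", "rsB"]
        np.testing.assert_array_equal(back.dosages, g.dosages)
        assert back.sample_ids == g.sample_ids

    def test_round_trip_simulated_matrix(self, tmp_path):
        g = simulate_genotypes(SimConfig(n_individuals=100, n_snps=50,
                                         n_causal=10, seed=3))
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        np.testing.assert_array_equal(read_genotypes(path).dosages, g.dosages)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tsA\tsB\ni1\t0\t1\ni2\t3\t1\n")
        with pytest.raises(ValueError, match=r"bad\.tsv:3.*'3'.*'sA'"):
            read_genotypes(path)

    def test_vcf_gt_to_dosage(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        path = tmp_path / "t.vcf"
        path.write_text(vcf_text)
        g = read_genotypes(path, format="vcf")
        assert g.snp_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(g.dosages, [[1, 0], [2, 1], [0, 2]])

    def test_multiallelic_vcf_site_is_an_error(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\n"
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t1/2\n"
        )
        path = tmp_path / "m.vcf"
        path.write_text(vcf_text)
        with pytest.raises(ValueError, match="multi-allelic"):
            read_genotypes(path, format="vcf")

    def test_phenotype_round_trip(self, tmp_path):
        ph = PhenotypeTable(["a", "b"], [1, 0], [0, 1], [1, 1], [30.5, 61.0])
        path = tmp_path / "ph.tsv"
        write_phenotypes(ph, path)
        back = read_phenotypes(path)
        assert back.sample_ids == ["a", "b"]
        np.testing.assert_allclose(back.age, [30.5, 61.0])


class TestFilterMonomorphic:
    def test_constant_column_removed(self):
        g = _matrix([[0, 1], [0, 2], [0, 0]])
        filtered, removed = filter_monomorphic(g)
        assert removed == ["s0"] and filtered.snp_ids == ["s1"]

    def test_single_heterozygote_retained(self):
        col = np.zeros((100, 1), dtype=int)
        col[42] = 1
        filtered, removed = filter_monomorphic(_matrix(col))
        assert removed == [] and filtered.n_snps == 1

    def test_planted_constant_columns_exactly_removed(self, rng):
        m = rng.integers(0, 3, size=(60, 40))
        planted = sorted(rng.choice(40, size=7, replace=False))
        for j in planted:
            m[:, j] = 1
        # re-randomize any accidentally constant non-planted column
        for j in range(40):
            if j not in planted and len(np.unique(m[:, j])) < 2:
                m[0, j], m[1, j] = 0, 1
        _, removed = filter_monomorphic(_matrix(m))
        assert removed == [f"s{j}" for j in planted]

    def test_counts_partition_and_causal_accounting(self, rng):
        causal = np.zeros(20, dtype=bool)
        causal[:6] = True
        m = rng.integers(0, 3, size=(50, 20))
        m[:, 3] = 0
        g = _matrix(m, causal=causal)
        filtered, removed = filter_monomorphic(g)
        assert filtered.n_snps + len(removed) == 20
        assert len(filtered.causal_snp_ids()) == int(
            causal[[j for j in range(20) if f"s{j}" not in removed]].sum())

    def test_idempotent(self, rng):
        g = _matrix(rng.integers(0, 3, size=(30, 15)))
        once, _ = filter_monomorphic(g)
        twice, removed_again = filter_monomorphic(once)
        assert removed_again == [] and twice.snp_ids == once.snp_ids

    def test_subset_restriction_and_errors(self):
        g = _matrix([[0, 1], [1, 1], [2, 0]])
        filtered, removed = filter_monomorphic(g, ["i0", "i1"])
        assert removed == ["s1"] and filtered.n_samples == 2
        with pytest.raises(ValueError, match="non-empty"):
            filter_monomorphic(g, [])

    def test_pool_then_filter_retains_superset_of_single_parts(self, small_study):
        _, reps = small_study
        pooled, _ = pool_datasets(reps)
        pooled_kept = set(filter_monomorphic(pooled)[0].snp_ids)
        for g, _ph in reps:
            kept = set(filter_monomorphic(g)[0].snp_ids)
            assert kept <= pooled_kept


class TestAgeBinning:
    def test_eight_point_example(self):
        assert bin_age_quartiles(range(1, 9)).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_all_equal_collapses_to_bin_zero(self):
        assert bin_age_quartiles([40.0] * 10).tolist() == [0] * 10

    def test_uniform_ages_balance_within_ties(self, rng):
        ages = rng.uniform(20, 80, size=1000)
        counts = np.bincount(bin_age_quartiles(ages), minlength=4)
        assert counts.tolist() == [250, 250, 250, 250]

    def test_non_finite_age_errors(self):
        with pytest.raises(ValueError, match="finite"):
            bin_age_quartiles([30.0, np.nan])
        with pytest.raises(ValueError, match="non-empty"):
            bin_age_quartiles([])

    @given(st.lists(st.floats(0, 120, allow_nan=False), min_size=4, max_size=40),
           st.randoms(use_true_random=False))
    def test_bins_follow_values_not_positions(self, ages, pyrandom):
        perm = list(range(len(ages)))
        pyrandom.shuffle(perm)
        base = bin_age_quartiles(ages)
        shuffled = bin_age_quartiles([ages[i] for i in perm])
        assert all(shuffled[j] == base[perm[j]] for j in range(len(ages)))


class TestPooling:
    def test_sizes_add(self, small_study):
        _, reps = small_study
        g, ph = pool_datasets(reps[:2])
        assert g.n_samples == ph.n_samples == 2 * reps[0][0].n_samples

    def test_pooling_replicate_with_itself_duplicates_rows(self, small_study):
        _, reps = small_study
        g, _ = pool_datasets([reps[0], reps[0]])
        n = reps[0][0].n_samples
        np.testing.assert_array_equal(g.dosages[:n], g.dosages[n:])

    def test_replicates_share_genotypes_but_not_outcomes(self, small_study):
        _, reps = small_study
        g, ph = pool_datasets(reps)
        n = reps[0][0].n_samples
        blocks = [g.dosages[i * n:(i + 1) * n] for i in range(len(reps))]
        for block in blocks[1:]:
            np.testing.assert_array_equal(block, blocks[0])
        affected = [ph.affected[i * n:(i + 1) * n] for i in range(len(reps))]
        assert any(not np.array_equal(affected[0], a) for a in affected[1:])

    def test_snp_mismatch_lists_symmetric_difference(self):
        g1 = _matrix([[0, 1]], snp_ids=["a", "b"])
        g2 = _matrix([[0, 1]], snp_ids=["a", "c"])
        ph = PhenotypeTable(["i0"], [1], [0], [0], [40.0])
        with pytest.raises(ValueError, match=r"\['b', 'c'\]"):
            pool_datasets([(g1, ph), (g2, ph)])


class TestLd:
    def test_identical_columns_give_perfect_ld(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        g = _matrix(np.column_stack([col, col]))
        res = ld_pairwise(g, "s0", "s1")
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.d_prime == pytest.approx(1.0, abs=1e-9)

    def test_singleton_allele_forces_d_prime_one(self, rng):
        """An allele on a single chromosome has an obligate zero cell in
        the 2x2 haplotype table, so |D'| = 1 against any other SNP."""
        b = rng.integers(0, 3, size=50)
        b[0] = 0  # singleton carrier unambiguous at the second locus
        a = np.zeros(50, dtype=int)
        a[0] = 1
        g = _matrix(np.column_stack([a, b]))
        res = ld_pairwise(g, "s0", "s1")
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)
        assert res.r2 < 0.2

    def test_independent_snps_have_tiny_r2(self, rng):
        n = 10_000
        a = rng.binomial(2, 0.3, n)
        b = rng.binomial(2, 0.2, n)
        res = ld_pairwise(_matrix(np.column_stack([a, b])), "s0", "s1")
        assert res.r2 < 0.01

    def test_monomorphic_input_errors(self):
        g = _matrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pairwise(g, "s0", "s1")

    def test_em_matches_phased_haplotype_counts(self, rng):
        """On genotypes without double heterozygotes the phase is known,
        so EM must reproduce the direct haplotype-count D exactly."""
        for _ in range(10):
            hap_freqs = rng.dirichlet([2, 1, 1, 2])
            haps = rng.choice(4, size=(4000, 2), p=hap_freqs)  # 11,10,01,00
            a_al = np.isin(haps, (0, 1)).astype(int)
            b_al = np.isin(haps, (0, 2)).astype(int)
            a, b = a_al.sum(axis=1), b_al.sum(axis=1)
            keep = ~((a == 1) & (b == 1))
            a, b = a[keep], b[keep]
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            n_hap = 2 * len(a)
            p11 = np.minimum(a, b).sum() / n_hap
            D_direct = p11 - (a.sum() / n_hap) * (b.sum() / n_hap)
            res = ld_pairwise(_matrix(np.column_stack([a, b])), "s0", "s1")
            pA, pB = a.sum() / n_hap, b.sum() / n_hap
            r2_direct = D_direct ** 2 / (pA * (1 - pA) * pB * (1 - pB))
            assert res.r2 == pytest.approx(r2_direct, abs=1e-6)


def test_dosage_validation_names_offending_cell():
    with pytest.raises(ValueError, match="i1.*s0"):
        _matrix([[0, 1], [3, 1]])
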