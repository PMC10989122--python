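"""Synthetic-cohort generator: planted structure, truth, determinism."""

import numpy as np
import pytest

from pansvkit import selection, simulate
from pansvkit.simulate import SimulationConfig


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.5)

    def test_bad_planted_af(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_svs=((0.1, 1.2, 0.0),))

    def test_small_group(self):
        with pytest.raises(ValueError):
            SimulationConfig(group_sizes=(("wild", 1), ("native", 5)))

    def test_f2_variance_budget(self):
        with pytest.raises(ValueError):
            simulate.F2Config(v=0.95, sex_var=0.1)


class TestGenotypes:
    def test_planted_af_realized_within_binomial_error(self):
        cfg = SimulationConfig(seed=11, n_sv=300,
                               planted_svs=((0.05, 0.89, 0.012),))
        matrix, metadata, truth = simulate.simulate_cohort_genotypes(cfg)
        (sv_id,) = truth["planted"]
        counts = selection.group_allele_counts(matrix, metadata)
        j = [r.id for r in matrix.records].index(sv_id)
        # binomial SE at n=70 diploids is sqrt(.89*.11/140) ~ 0.026
        assert abs(counts["native"].af[j] - 0.89) < 0.06
        assert abs(counts["wild"].af[j] - 0.05) < 0.12
        assert abs(counts["commercial"].af[j] - 0.012) < 0.06

    def test_null_svs_share_frequency_across_groups(self):
        cfg = SimulationConfig(seed=3, n_sv=2000, planted_svs=())
        matrix, metadata, truth = simulate.simulate_cohort_genotypes(cfg)
        counts = selection.group_allele_counts(matrix, metadata)
        diff = counts["wild"].af - counts["commercial"].af
        # shared AF => mean difference ~ 0 across many null sites
        assert abs(np.nanmean(diff)) < 0.01

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(seed=5, n_sv=100)
        m1, _, _ = simulate.simulate_cohort_genotypes(cfg)
        m2, _, _ = simulate.simulate_cohort_genotypes(cfg)
        assert np.array_equal(m1.dosages, m2.dosages)
        assert m1.records == m2.records

    def test_group_sizes(self, small_cohort):
        groups = {}
        for m in small_cohort.metadata:
            groups[m.group] = groups.get(m.group, 0) + 1
        assert groups == {"wild": 20, "native": 70, "commercial": 41}


class TestLandscape:
    def test_intact_fraction_exact_count(self):
        cfg = SimulationConfig(seed=2, n_sv=100, intact_fraction=0.1)
        tes, records, intact_ids = simulate.simulate_te_sv_landscape(cfg)
        assert len(intact_ids) == 10
        assert len(records) == 100

    def test_intact_derived_reciprocal_overlap_above_95(self):
        cfg = SimulationConfig(seed=2, n_sv=100, intact_fraction=0.1)
        tes, records, intact_ids = simulate.simulate_te_sv_landscape(cfg)
        intact_tes = [t for t in tes if t.intact]
        by_id = {r.id: r for r in records}
        for sv_id in intact_ids:
            iv = by_id[sv_id].interval
            best = max(
                min(iv.overlap_bp(t.interval) / len(iv),
                    iv.overlap_bp(t.interval) / len(t.interval))
                for t in intact_tes)
            assert best > 0.95

    def test_sv_bounds_respect_layout(self):
        cfg = SimulationConfig(seed=9, n_sv=500, rho=0.9)
        tes, records, _ = simulate.simulate_te_sv_landscape(cfg)
        for r in records:
            assert r.interval.end <= cfg.layout.length_of(r.interval.chrom)


class TestLtrPairs:
    def test_k_zero_identical(self, rng):
        seq = simulate.random_sequence(500, rng)
        a, b = simulate.simulate_ltr_pair(seq, 0.0, rng)
        assert a == b == seq

    def test_observed_divergence_matches_k(self, rng):
        seq = simulate.random_sequence(10_000, rng)
        a, b = simulate.simulate_ltr_pair(seq, 0.01, rng)
        mism = sum(x != y for x, y in zip(a, b)) / len(seq)
        assert abs(mism - 0.01) < 0.003  # ~3 binomial SE

    def test_k_above_jc_validity_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate.simulate_ltr_pair("A" * 200, 0.8, rng)

    def test_short_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate.simulate_ltr_pair("ACGT" * 10, 0.01, rng)


class TestPavCoverage:
    def test_present_gene_nearly_fully_covered(self, small_cohort):
        cov = small_cohort.coverage
        truth = small_cohort.pav_truth.to_frame()
        frac = (cov.groupby(["gene", "sample"])
                [["bases_ge_min_depth", "exon_length"]].sum())
        frac = (frac.bases_ge_min_depth / frac.exon_length).unstack()
        frac = frac.reindex(index=truth.index, columns=truth.columns)
        present = frac.to_numpy()[truth.to_numpy() == 1]
        absent = frac.to_numpy()[truth.to_numpy() == 0]
        assert present.min() > 0.95
        assert absent.size and absent.mean() < 0.05 and absent.mean() > 0.0

    def test_zero_depth_means_all_absent(self):
        cfg = SimulationConfig(seed=1, n_genes=10, coverage_depth=0.0)
        cov, truth, genes = simulate.simulate_pav_coverage(cfg)
        assert (cov.bases_ge_min_depth == 0).all()


class TestF2:
    def test_v_zero_means_no_additive_effect(self):
        cfg = SimulationConfig(seed=1, f2=simulate.F2Config(v=0.0))
        pheno, marker, truth = simulate.simulate_f2(cfg)
        assert truth["additive_effect"] == 0.0

    def test_f2_segregation_ratio(self):
        cfg = SimulationConfig(seed=4, f2=simulate.F2Config(n=2000))
        _, marker, _ = simulate.simulate_f2(cfg)
        freq = np.bincount(marker, minlength=3) / len(marker)
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=0.04)


class TestWindowHaplotypes:
    def test_zero_sites(self, rng):
        pos, mat = simulate.simulate_window_haplotypes(10, 0, 1000, rng)
        assert pos.size == 0 and mat.shape == (0, 10)

    def test_sfs_proportional_to_inverse_frequency(self):
        rng = np.random.default_rng(77)
        n = 10
        pos, mat = simulate.simulate_window_haplotypes(n, 20_000, 50_000,
                                                       rng)
        counts = mat.sum(axis=1)
        hist = np.bincount(counts, minlength=n)[1:n]
        i = np.arange(1, n)
        expected = (1.0 / i) / np.sum(1.0 / i) * len(counts)
        # chi-square goodness of fit against the neutral SFS
        chi2 = np.sum((hist - expected) ** 2 / expected)
        from scipy.stats import chi2 as chi2_dist
        assert chi2_dist.sf(chi2, df=n - 2) > 0.001

    def test_determinism(self):
        r1 = np.random.default_rng(5)
        r2 = np.random.default_rng(5)
        p1, m1 = simulate.simulate_window_haplotypes(8, 50, 1000, r1)
        p2, m2 = simulate.simulate_window_haplotypes(8, 50, 1000, r2)
        assert np.array_equal(p1, p2) and np.array_equal(m1, m2)


def test_write_cohort_emits_all_files(tmp_path, small_cohort):
    simulate.write_cohort(small_cohort, tmp_path)
    expected = {"svs.vcf", "tes.bed", "genes.gff3", "coverage.tsv",
                "ltr_pairs.fasta", "phenotypes.tsv", "groups.tsv",
                "layout.tsv", "pav_truth.tsv", "truth.json"}
    assert expected <= {p.name for p in tmp_path.iterdir()}
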