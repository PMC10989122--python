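"""Fisher exact, BH, Weir-Cockerham F_ST, selection scan, dAF ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from oracles import wc84_oracle

from pansvkit import selection, simulate
from pansvkit.io import MISSING, SampleMetadata, SvGenotypeMatrix, SvRecord
from pansvkit.regions import GenomeLayout, Interval
from pansvkit.simulate import SimulationConfig


class TestGroupAlleleCounts:
    def make_matrix(self, dosages):
        dosages = np.asarray(dosages, dtype=np.int8)
        n = dosages.shape[0]
        recs = [SvRecord("sv1", Interval("chr1", 100, 200), "DEL", 100)]
        samples = [f"s{i}" for i in range(n)]
        meta = [SampleMetadata(s, "g1") for s in samples]
        return SvGenotypeMatrix(recs, samples, dosages), meta

    def test_all_hets(self):
        m, meta = self.make_matrix([[1]] * 10)
        c = selection.group_allele_counts(m, meta)["g1"]
        assert (c.d[0], c.m[0], c.h[0]) == (10, 20, 10)

    def test_missing_excluded(self):
        m, meta = self.make_matrix([[1]] * 9 + [[MISSING]])
        c = selection.group_allele_counts(m, meta)["g1"]
        assert (c.m[0], c.n[0]) == (18, 9)

    def test_all_missing(self):
        m, meta = self.make_matrix([[MISSING]] * 5)
        c = selection.group_allele_counts(m, meta)["g1"]
        assert c.m[0] == 0 and np.isnan(c.af[0])


class TestMafFilter:
    def make(self, afs, n=100, seed=0):
        rng = np.random.default_rng(seed)
        recs = [SvRecord(f"sv{j}", Interval("chr1", 100 * (j + 1),
                                            100 * (j + 1) + 60), "DEL", 60)
                for j in range(len(afs))]
        dos = np.column_stack([rng.binomial(2, af, size=n) for af in afs])
        return SvGenotypeMatrix(recs, [f"s{i}" for i in range(n)],
                                dos.astype(np.int8))

    def test_rare_and_common(self):
        recs = [SvRecord(f"sv{j}", Interval("chr1", 100 * (j + 1),
                                            100 * (j + 1) + 60), "DEL", 60)
                for j in range(3)]
        # exact pooled AFs 0.005, 0.5, 0.995 over 100 diploids
        col0 = np.array([1] + [0] * 99)
        col1 = np.array([1] * 100)
        col2 = np.array([1] + [2] * 99)
        m = SvGenotypeMatrix(recs, [f"s{i}" for i in range(100)],
                             np.column_stack([col0, col1, col2]).astype(
                                 np.int8))
        kept = selection.maf_filter(m, min_maf=0.01)
        assert [r.id for r in kept.records] == ["sv1"]


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        (((5, 5), (5, 5)), 1.0),
        (((3, 1), (1, 3)), 34 / 70),
        (((10, 0), (0, 10)), 2 / 184756),
    ])
    def test_worked_examples(self, table, expected):
        assert selection.fisher_exact_two_sided(table) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            selection.fisher_exact_two_sided(((1, -1), (0, 2)))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 30, size=4)
            ours = selection.fisher_exact_two_sided(
                ((t[0], t[1]), (t[2], t[3])))
            ref = scipy_fisher([[t[0], t[1]], [t[2], t[3]]],
                               alternative="two-sided")[1]
            assert ours == pytest.approx(min(ref, 1.0), rel=1e-6)


class TestBhAdjust:
    def test_single_p(self):
        assert selection.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up(self):
        q = selection.bh_adjust([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(q, [0.004, 0.02, 4 * 0.02 / 3, 0.8])

    def test_all_equal(self):
        q = selection.bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(100)
        q = selection.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            selection.bh_adjust([0.5, 1.5])


class TestWcFst:
    def counts(self, n1, d1, h1, n2, d2, h2):
        g1 = selection.GroupAlleleCounts("a", np.array([d1]),
                                         np.array([2 * n1]),
                                         np.array([h1]), np.array([n1]))
        g2 = selection.GroupAlleleCounts("b", np.array([d2]),
                                         np.array([2 * n2]),
                                         np.array([h2]), np.array([n2]))
        return {"a": g1, "b": g2}

    def test_fixed_difference_is_one(self):
        theta, *_ = selection.wc_fst(self.counts(10, 20, 0, 10, 0, 0))
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_all_het_groups_is_zero(self):
        # p = 0.5 with every individual heterozygous: h = 4p(1-p), the
        # configuration where the estimator is exactly zero
        theta, *_ = selection.wc_fst(self.counts(10, 10, 10, 10, 10, 10))
        assert theta[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_hwe_groups_finite_sample_bias(self):
        # equal HWE groups give theta = -1/(2(n-1)), approaching 0 with n
        n, p = 10, 0.5
        h = int(2 * p * (1 - p) * n)  # 5 hets of 10
        theta, *_ = selection.wc_fst(
            self.counts(n, int(2 * n * p), h, n, int(2 * n * p), h))
        assert theta[0] == pytest.approx(-1 / (2 * (n - 1)), abs=1e-12)

    def test_worked_genotype_example_matches_oracle(self):
        # (4 AA, 4 Aa, 2 aa) vs (2 AA, 4 Aa, 4 aa), n = 10 each
        theta, a, b, c = selection.wc_fst(
            self.counts(10, 12, 4, 10, 8, 4))
        ao, bo, co = wc84_oracle([10, 10], [0.6, 0.4], [0.4, 0.4])
        assert theta[0] == pytest.approx(ao / (ao + bo + co), abs=1e-12)

    def test_symmetric_under_group_swap(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, size=2)
            d1 = rng.integers(0, 2 * n1 + 1)
            d2 = rng.integers(0, 2 * n2 + 1)
            h1 = rng.integers(0, min(d1, 2 * n1 - d1) + 1)
            h2 = rng.integers(0, min(d2, 2 * n2 - d2) + 1)
            t1, *_ = selection.wc_fst(self.counts(n1, d1, h1, n2, d2, h2))
            t2, *_ = selection.wc_fst(self.counts(n2, d2, h2, n1, d1, h1))
            if np.isnan(t1[0]):
                assert np.isnan(t2[0])
            else:
                assert t1[0] == pytest.approx(t2[0], abs=1e-12)

    def test_invariant_under_allele_relabeling(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, size=2)
            d1 = rng.integers(0, 2 * n1 + 1)
            d2 = rng.integers(0, 2 * n2 + 1)
            h1 = rng.integers(0, min(d1, 2 * n1 - d1) + 1)
            h2 = rng.integers(0, min(d2, 2 * n2 - d2) + 1)
            t1, *_ = selection.wc_fst(self.counts(n1, d1, h1, n2, d2, h2))
            t2, *_ = selection.wc_fst(self.counts(n1, 2 * n1 - d1, h1,
                                                  n2, 2 * n2 - d2, h2))
            if not np.isnan(t1[0]):
                assert t1[0] == pytest.approx(t2[0], abs=1e-12)

    def test_monomorphic_is_missing(self):
        theta, *_ = selection.wc_fst(self.counts(10, 0, 0, 10, 0, 0))
        assert np.isnan(theta[0])


class TestScanSelection:
    def test_planted_sv_selected_with_direction(self):
        cfg = SimulationConfig(seed=21, n_sv=500,
                               planted_svs=((0.85, 0.89, 0.012),))
        matrix, meta, truth = simulate.simulate_cohort_genotypes(cfg)
        matrix = selection.maf_filter(matrix)
        res = selection.scan_selection(matrix, meta,
                                       ("native", "commercial"))
        (planted,) = truth["planted"]
        row = res[res.sv_id == planted].iloc[0]
        assert row.selected and row.direction == "decreased"

    def test_equal_afs_direction_none(self):
        recs = [SvRecord("sv1", Interval("chr1", 100, 160), "DEL", 60)]
        dos = np.array([[1]] * 4 + [[1]] * 4, dtype=np.int8)
        samples = [f"s{i}" for i in range(8)]
        meta = [SampleMetadata(s, "a" if i < 4 else "b")
                for i, s in enumerate(samples)]
        m = SvGenotypeMatrix(recs, samples, dos)
        res = selection.scan_selection(m, meta, ("a", "b"))
        assert res.direction.iloc[0] == "none"

    def test_unknown_group_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            selection.scan_selection(small_cohort.sv_matrix,
                                     small_cohort.metadata,
                                     ("native", "nope"))


class TestDeltaAf:
    def test_planted_variant_ranks_first(self):
        cfg = SimulationConfig(seed=31, n_sv=90, planted_svs=())
        matrix, meta, _ = simulate.simulate_cohort_genotypes(cfg)
        # plant a 0.9-vs-0.0 difference at a known record
        target = matrix.records[10]
        planted = {target.id: (0.5, 0.9, 0.0)}
        matrix, meta, _ = simulate.simulate_cohort_genotypes(
            cfg, records=matrix.records, planted=planted)
        region = Interval(target.interval.chrom, 1, 5_000_000)
        res = selection.delta_af(matrix, meta, "native", "commercial",
                                 region)
        assert res.iloc[0].variant == target.id
        assert res.iloc[0].delta_af > 0.8
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))

    def test_empty_region_warns(self, small_cohort):
        with pytest.warns(UserWarning):
            res = selection.delta_af(small_cohort.sv_matrix,
                                     small_cohort.metadata,
                                     "native", "commercial",
                                     Interval("chr1", 1, 2))
        assert res.empty
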