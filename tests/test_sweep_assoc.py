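"""Diversity statistics, Tajima's D, windowed scans, marker association."""

import numpy as np
import pytest

from pansvkit import simulate, sweep
from pansvkit.io import MISSING
from oracles import pi_oracle, tajima_oracle


class TestPi:
    def test_worked_example_four_haplotypes(self):
        # one 2/2 site in a 100 bp window: 2*0.5*0.5*(4/3)/100
        hap = np.array([[1, 1, 0, 0]]).T.reshape(1, 4)
        assert sweep.pi_per_site(hap, 100) == pytest.approx(2 / 3 / 100,
                                                            rel=1e-12)

    def test_no_segregating_sites(self):
        hap = np.zeros((5, 6), dtype=int)
        assert sweep.pi_per_site(hap, 100) == 0.0

    def test_two_identical_haplotypes(self):
        hap = np.array([[1, 1], [0, 0], [1, 1]])
        assert sweep.pi_per_site(hap, 50) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            hap = (rng.random((50, 12)) < 0.3).astype(int)
            assert sweep.pi_per_site(hap, 1000) == pytest.approx(
                pi_oracle(hap, 1000), rel=1e-12, abs=1e-15)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            sweep.pi_window([1], [4], 0)


class TestTajimasD:
    def test_no_sites_missing(self):
        comp = sweep.tajimas_d(np.zeros((3, 6), dtype=int))
        assert comp.S == 0 and np.isnan(comp.D)

    def test_worked_value_n4_single_site(self):
        hap = np.array([[1, 1, 0, 0]])
        comp = sweep.tajimas_d(hap)
        assert comp.kbar == pytest.approx(2 / 3, rel=1e-12)
        assert comp.a1 == pytest.approx(11 / 6, rel=1e-12)
        # D = (2/3 - 6/11) / sqrt(e1) = (4/33)/(sqrt(6)/33) = 4/sqrt(6)
        assert comp.D == pytest.approx(4 / np.sqrt(6), rel=1e-12)
        assert comp.D == pytest.approx(tajima_oracle(hap), rel=1e-12)

    def test_allele_relabel_invariance(self, rng):
        hap = (rng.random((30, 10)) < 0.4).astype(int)
        d1 = sweep.tajimas_d(hap).D
        flip = rng.random(30) < 0.5
        hap2 = hap.copy()
        hap2[flip] = 1 - hap2[flip]
        assert sweep.tajimas_d(hap2).D == pytest.approx(d1, rel=1e-12)

    def test_matches_oracle_random_windows(self, rng):
        for _ in range(20):
            hap = (rng.random((50, 8)) < rng.uniform(0.1, 0.6)).astype(int)
            ours = sweep.tajimas_d(hap).D
            ref = tajima_oracle(hap)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, rel=1e-12)

    def test_fewer_than_four_haplotypes(self):
        with pytest.raises(ValueError):
            sweep.tajimas_d(np.array([[1, 0, 0]]))

    def test_neutral_simulation_near_zero(self):
        rng = np.random.default_rng(42)
        ds = []
        for _ in range(50):
            _, hap = simulate.simulate_window_haplotypes(20, 30, 10_000,
                                                         rng)
            ds.append(sweep.tajimas_d(hap).D)
        assert abs(np.mean(ds)) < 0.3


class TestWindowedScan:
    def test_window_counts_match_presets(self, rng):
        pos = rng.integers(0, 100_000, size=200)
        hap = (rng.random((200, 10)) < 0.3).astype(int)
        df_pi = sweep.windowed_scan(pos, hap, 100_000, "pi")
        assert len(df_pi) == 5
        df_d = sweep.windowed_scan(pos, hap, 100_000, "tajima_d")
        assert len(df_d) == 19

    def test_empty_window_missing(self):
        pos = np.array([5])
        hap = np.array([[1, 0, 1, 0]])
        df = sweep.windowed_scan(pos, hap, 40_000, "pi",
                                 window=20_000, step=20_000)
        assert not np.isnan(df.value.iloc[0])
        assert np.isnan(df.value.iloc[1])

    def test_single_site_window_fst_equals_single_locus(self, rng):
        from pansvkit import selection
        dosages = rng.integers(0, 3, size=(1, 40)).astype(np.int8)
        groups = np.repeat([0, 1], 20)
        df = sweep.windowed_scan([100], dosages, 1000, "fst",
                                 window=1000, step=1000,
                                 group_index=groups)
        g1 = dosages[0, :20]
        g2 = dosages[0, 20:]
        c = {}
        for name, dd in (("a", g1), ("b", g2)):
            c[name] = selection.GroupAlleleCounts(
                name, np.array([dd.sum()]), np.array([2 * dd.size]),
                np.array([(dd == 1).sum()]), np.array([dd.size]))
        theta, *_ = selection.wc_fst(c)
        assert df.value.iloc[0] == pytest.approx(theta[0], rel=1e-12)

    def test_fst_peak_at_planted_sweep_region(self):
        """Near-fixed differentiation in one 20 kb region dominates the
        windowed F_ST scan in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n_sites, n1, n2 = 300, 40, 40
            pos = np.sort(rng.choice(100_000, size=n_sites, replace=False))
            af = rng.beta(0.8, 0.8, size=n_sites)
            in_region = (pos >= 40_000) & (pos < 60_000)
            dos = np.empty((n_sites, n1 + n2), dtype=np.int8)
            for i in range(n_sites):
                p1, p2 = af[i], af[i]
                if in_region[i]:
                    p1, p2 = 0.97, 0.03
                dos[i, :n1] = rng.binomial(2, p1, size=n1)
                dos[i, n1:] = rng.binomial(2, p2, size=n2)
            df = sweep.windowed_scan(pos, dos, 100_000, "fst",
                                     group_index=np.repeat([0, 1],
                                                           [n1, n2]))
            peak = df.loc[df.value.idxmax()]
            if 40_000 <= peak.start < 60_000:
                hits += 1
        assert hits >= 9


class TestSingleMarkerGlm:
    def test_noiseless_marker_r2_is_one(self):
        g = np.repeat([0, 1, 2], 20)
        sex = np.tile([0, 1], 30)  # balanced within genotype classes
        y = g.astype(float)
        res = sweep.single_marker_glm(y, g, sex)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.p < 1e-30

    def test_sex_only_signal_gives_null_marker(self):
        rng = np.random.default_rng(0)
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sex = rng.integers(0, 2, 500)
            g = rng.choice([0, 1, 2], 500, p=[0.25, 0.5, 0.25])
            y = 2.0 * sex + rng.normal(size=500)
            r2s.append(sweep.single_marker_glm(y, g, sex).r2)
        assert np.mean(r2s) < 0.01

    def test_f2_variance_fraction_recovery(self):
        r2s = []
        for seed in range(20):
            cfg = simulate.SimulationConfig(seed=seed)
            pheno, marker, truth = simulate.simulate_f2(cfg)
            res = sweep.single_marker_glm(pheno.weight, marker, pheno.sex)
            r2s.append(res.r2)
        assert abs(np.mean(r2s) - 0.2761) < 0.05

    def test_genotype_class_model(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0, 1, 2], 300, p=[0.25, 0.5, 0.25])
        sex = rng.integers(0, 2, 300)
        y = 1.5 * (g == 2) + rng.normal(size=300)  # non-additive signal
        res = sweep.single_marker_glm(y, g, sex, model="genotype")
        assert res.p < 1e-6 and 0 <= res.r2 <= 1

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError):
            sweep.single_marker_glm(np.ones(20), np.ones(20),
                                    np.zeros(20))

    def test_missing_denominator_option(self, rng):
        pos = rng.integers(0, 20_000, size=50)
        hap = (rng.random((50, 8)) < 0.3).astype(int)
        by_window = sweep.windowed_scan(pos, hap, 20_000, "pi",
                                        window=20_000, step=20_000)
        by_sites = sweep.windowed_scan(pos, hap, 20_000, "pi",
                                       window=20_000, step=20_000,
                                       denominator="sites")
        assert by_sites.value.iloc[0] > by_window.value.iloc[0]
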