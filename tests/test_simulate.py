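import numpy as np
import pytest

from astwas.genotype import GeneRegion
from astwas.simulate import (
    ARCHITECTURES,
    ScenarioInfeasibleError,
    SimScenario,
    add_environmental_noise,
    apply_effect,
    binarize_liability,
    genetic_value,
    n_causal_for,
    select_causal_snps,
    simulate_dataset,
    simulate_genotypes,
    simulate_null_dataset,
)


class TestGenotypeGenerator:
    def test_mean_dosage_tracks_maf(self):
        gm = simulate_genotypes(50_000, 2, maf_spec=0.5, ld_rho=0.0, seed=1)
        assert gm.dosages.mean(axis=0) == pytest.approx(1.0, abs=0.02)

    def test_high_ld_adjacent_pair(self):
        gm = simulate_genotypes(50_000, 2, maf_spec=0.3, ld_rho=0.99, seed=2)
        r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
        assert r * r > 0.8

    def test_low_maf_band(self):
        gm = simulate_genotypes(5_000, 10, maf_spec=0.05, ld_rho=0.0, seed=3)
        mafs = np.array([v.maf for v in gm.variants])
        assert np.all((mafs >= 0.03) & (mafs <= 0.07))

    def test_dosage_alphabet_and_determinism(self):
        gm1 = simulate_genotypes(200, 5, (0.05, 0.5), 0.3, seed=7)
        gm2 = simulate_genotypes(200, 5, (0.05, 0.5), 0.3, seed=7)
        assert set(np.unique(gm1.dosages)) <= {0.0, 1.0, 2.0}
        np.testing.assert_array_equal(gm1.dosages, gm2.dosages)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 2, maf_spec=0.01)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 2, ld_rho=1.0)


class TestCausalSelection:
    def test_forced_choice_and_determinism(self):
        gm = simulate_genotypes(50, 2, 0.3, 0.0, seed=4)
        picked = select_causal_snps(gm, None, 2, "random", seed=0)
        assert sorted(picked) == ["snp0", "snp1"]

    def test_high_ld_finds_duplicated_pair(self, rng):
        gm = simulate_genotypes(100, 4, 0.3, 0.0, seed=5)
        gm.dosages[:, 3] = gm.dosages[:, 0]  # r^2 = 1 pair
        picked = select_causal_snps(gm, None, 2, "high_ld", seed=1)
        assert set(picked) == {"snp0", "snp3"}

    def test_low_ld_infeasible_reports_best(self):
        gm = simulate_genotypes(100, 3, 0.3, 0.0, seed=6)
        gm.dosages[:, 1] = gm.dosages[:, 0]
        gm.dosages[:, 2] = gm.dosages[:, 0]
        with pytest.raises(ScenarioInfeasibleError, match="best available"):
            select_causal_snps(gm, None, 2, "low_ld", seed=1)

    def test_respects_cis_window(self):
        gm = simulate_genotypes(50, 10, 0.3, 0.0, seed=8, position_step=40_000)
        region = GeneRegion("g", "1", 1)  # window [1, 150001]: snp0..snp3
        for _ in range(5):
            picked = select_causal_snps(gm, region, 2, "random", seed=_)
            assert set(picked) <= {"snp0", "snp1", "snp2", "snp3"}


class TestArchitectures:
    @pytest.mark.parametrize("arch, expected", [
        ("epistatic", lambda a, b: float(a >= 1 and b >= 1)),
        ("heterogeneous", lambda a, b: float(a >= 1 or b >= 1)),
        ("compensatory", lambda a, b: float((a >= 1) != (b >= 1))),
    ])
    def test_truth_tables_over_all_dosage_pairs(self, arch, expected):
        pairs = [(a, b) for a in (0, 1, 2) for b in (0, 1, 2)]
        X = np.array(pairs, dtype=float)
        g, _ = genetic_value(X, arch, seed=0)
        np.testing.assert_array_equal(g, [expected(a, b) for a, b in pairs])

    def test_single_is_carrier_indicator(self):
        g, _ = genetic_value(np.array([[0.0], [1.0], [2.0]]), "single")
        np.testing.assert_array_equal(g, [0.0, 1.0, 1.0])

    def test_additive_weighted_sum_reproducible(self):
        X = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        g, spec = genetic_value(X, "additive2", seed=42)
        w = np.random.default_rng(42).standard_normal(2)
        np.testing.assert_allclose(g, X @ w)
        np.testing.assert_allclose(apply_effect(X, spec), g)

    def test_causal_count_mismatch(self):
        with pytest.raises(ValueError, match="causal"):
            genetic_value(np.zeros((3, 3)), "epistatic")

    def test_n_causal_mapping(self):
        assert [n_causal_for(a) for a in ARCHITECTURES] == [2, 5, 10, 1, 2, 2, 2]


class TestHeritability:
    def test_variance_algebra(self, rng):
        g = rng.standard_normal(1000)
        g = g / g.std()  # sigma_g^2 = 1
        _, spec = add_environmental_noise(g, 0.5, seed=1)
        assert spec.sigma_e2 == pytest.approx(spec.sigma_g2)
        assert spec.sigma_p2 == pytest.approx(spec.sigma_g2 + spec.sigma_e2)

    def test_h2_one_is_noise_free(self, rng):
        g = rng.standard_normal(100)
        x, _ = add_environmental_noise(g, 1.0, seed=2)
        np.testing.assert_array_equal(x, g)

    def test_realized_heritability_recovery(self, rng):
        g = rng.standard_normal(20_000)
        x, _ = add_environmental_noise(g, 0.2, seed=3)
        realized = np.var(g) / np.var(x)
        assert 0.18 <= realized <= 0.22

    def test_constant_genetic_value_rejected(self):
        with pytest.raises(ScenarioInfeasibleError):
            add_environmental_noise(np.ones(10), 0.5)


class TestDatasets:
    def _scenario(self, **kw):
        base = dict(
            assumption="pleiotropy", architecture="epistatic",
            h2_pheno=0.1, h2_apa=0.1, n_samples=500, seed=13,
        )
        base.update(kw)
        return SimScenario(**base)

    def test_determinism_bit_identical(self):
        gm = simulate_genotypes(500, 12, (0.05, 0.5), 0.2, seed=9)
        sc = self._scenario()
        d1 = simulate_dataset(sc, gm)
        d2 = simulate_dataset(sc, gm)
        np.testing.assert_array_equal(d1.pdui, d2.pdui)
        np.testing.assert_array_equal(d1.phenotype, d2.phenotype)
        assert d1.causal_snp_ids == d2.causal_snp_ids

    def test_pleiotropy_shares_signal_with_independent_noise(self):
        gm = simulate_genotypes(2000, 12, (0.05, 0.5), 0.2, seed=10)
        ds = simulate_dataset(self._scenario(h2_pheno=0.5, h2_apa=0.5, n_samples=2000), gm)
        assert np.corrcoef(ds.pdui, ds.phenotype)[0, 1] > 0.2
        assert not np.array_equal(ds.pdui, ds.phenotype)

    def test_causality_noise_free_chain(self):
        gm = simulate_genotypes(300, 12, (0.05, 0.5), 0.2, seed=11)
        ds = simulate_dataset(
            self._scenario(assumption="causality", h2_pheno=1.0, h2_apa=1.0, n_samples=300), gm
        )
        idx = [gm.snp_ids.index(s) for s in ds.causal_snp_ids]
        g = apply_effect(gm.dosages[:, idx], ds.effect_spec)
        np.testing.assert_allclose(ds.phenotype, g)
        np.testing.assert_allclose(ds.pdui, g)

    def test_causality_infeasible_when_pheno_exceeds_apa(self):
        gm = simulate_genotypes(300, 12, (0.05, 0.5), 0.2, seed=12)
        with pytest.raises(ScenarioInfeasibleError, match="h2_pheno"):
            simulate_dataset(
                self._scenario(assumption="causality", h2_pheno=0.25, h2_apa=0.05, n_samples=300),
                gm,
            )

    def test_causal_snps_inside_window(self):
        gm = simulate_genotypes(300, 30, (0.05, 0.5), 0.2, seed=14, position_step=20_000)
        region = GeneRegion("g", "1", 200_000)
        ds = simulate_dataset(self._scenario(n_samples=300), gm, region=region)
        for sid in ds.causal_snp_ids:
            v = gm.variants[gm.snp_ids.index(sid)]
            assert region.window_lo <= v.position <= region.window_hi


class TestBinaryTraits:
    def test_median_split(self, rng):
        labels = binarize_liability(rng.standard_normal(100), 0.5)
        assert labels.sum() == 50

    def test_quantile_count(self, rng):
        labels = binarize_liability(rng.standard_normal(1000), 0.1)
        assert labels.sum() == 100

    def test_deterministic_and_threshold_direction(self, rng):
        x = rng.standard_normal(200)
        l1, l2 = binarize_liability(x, 0.3), binarize_liability(x, 0.3)
        np.testing.assert_array_equal(l1, l2)
        assert x[l1 == 1].min() > x[l1 == 0].max()  # cases are the upper tail


class TestNullDesign:
    def test_moments_and_determinism(self):
        data = simulate_null_dataset(50, 2000, seed=21)
        allvals = np.concatenate([np.concatenate(pair) for pair in data])
        assert allvals.mean() == pytest.approx(0.0, abs=0.02)
        assert allvals.std() == pytest.approx(1.0, abs=0.02)
        again = simulate_null_dataset(50, 2000, seed=21)
        np.testing.assert_array_equal(data[7][0], again[7][0])

    def test_transcriptome_phenotype_independence(self):
        data = simulate_null_dataset(200, 500, seed=22)
        rs = np.array([np.corrcoef(t, y)[0, 1] for t, y in data])
        # null correlation band: |r| < ~4.5/sqrt(n) for 200 draws
        assert np.max(np.abs(rs)) < 4.5 / np.sqrt(500)
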