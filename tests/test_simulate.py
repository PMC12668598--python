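import numpy as np
import pytest

from finemapmiss.io import ValidationError
from finemapmiss.overlap import build_meta_covariance
from finemapmiss.posterior import fine_map_meta
from finemapmiss.simulate import (LDSpec, SimConfig, degrade_to_dosages,
                                  inject_missingness, make_meta_dataset, run_gwas,
                                  sample_virtual_genotypes, simulate_genotypes,
                                  simulate_phenotype)
from tests.conftest import make_study


class TestGenotypes:
    def test_independent_variants_nearly_uncorrelated(self):
        n = 8000
        g, r_hat, _ = simulate_genotypes(6, n, LDSpec(block_size=1), seed=0)
        off = r_hat[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 4 / np.sqrt(n)

    def test_half_maf_mean_genotype_one(self):
        n = 8000
        g, _, model = simulate_genotypes(3, n, LDSpec(block_size=1),
                                         maf_range=np.array([0.5, 0.5, 0.5]), seed=1)
        assert np.max(np.abs(g.mean(axis=0) - 1.0)) < 4 / np.sqrt(n)

    def test_block_ld_calibrated_to_spec(self):
        n = 10_000
        spec = LDSpec(block_size=10, rho=0.9)
        _, r_hat, model = simulate_genotypes(20, n, spec, seed=2)
        assert np.max(np.abs(r_hat - model.target_r)) < 5 / np.sqrt(n)

    def test_same_seed_identical(self):
        g1, *_ = simulate_genotypes(8, 500, LDSpec(block_size=4), seed=3)
        g2, *_ = simulate_genotypes(8, 500, LDSpec(block_size=4), seed=3)
        assert np.array_equal(g1, g2)

    def test_infeasible_target_correlation_raises(self):
        # rare vs common variant cannot reach genotype correlation 0.95
        with pytest.raises(ValidationError, match="infeasible"):
            simulate_genotypes(2, 100, LDSpec(block_size=2, rho=0.95),
                               maf_range=np.array([0.02, 0.5]), seed=4)


class TestDosages:
    def test_info_one_reproduces_genotypes(self):
        g, _, model = simulate_genotypes(4, 2000, LDSpec(block_size=2), seed=5)
        dd = degrade_to_dosages(g, np.ones(4), model.maf)
        np.testing.assert_allclose(dd.dosages, g, atol=1e-6)
        np.testing.assert_allclose(dd.realized_info, 1.0, atol=1e-6)

    def test_realized_info_tracks_target(self):
        g, _, model = simulate_genotypes(6, 10_000, LDSpec(block_size=3), seed=6)
        target = np.array([0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        dd = degrade_to_dosages(g, target, model.maf)
        assert np.max(np.abs(dd.realized_info - target)) < 0.05

    def test_probability_triples_normalized_and_consistent(self):
        g, _, model = simulate_genotypes(3, 200, LDSpec(block_size=1), seed=7)
        dd = degrade_to_dosages(g, np.full(3, 0.7), model.maf, return_triples=True)
        np.testing.assert_allclose(dd.triples.sum(axis=-1), 1.0, atol=1e-12)
        # dosage is the expectation of the triple
        expect = dd.triples @ np.array([0.0, 1.0, 2.0])
        np.testing.assert_allclose(dd.dosages, expect, atol=1e-5)

    def test_bad_info_rejected(self):
        g = np.zeros((10, 1), dtype=np.int8)
        with pytest.raises(ValidationError):
            degrade_to_dosages(g, np.array([0.0]), np.array([0.3]))

    def test_virtual_genotype_dosage_correlation_is_sqrt_info(self):
        info = 0.6
        g, _, model = simulate_genotypes(1, 60_000, LDSpec(block_size=1), seed=8)
        dd = degrade_to_dosages(g, np.array([info]), model.maf)
        rng = np.random.default_rng(9)
        xv = sample_virtual_genotypes(g, dd.shrink, model.maf, rng)
        corr = np.corrcoef(xv[:, 0], dd.dosages[:, 0])[0, 1]
        assert corr == pytest.approx(np.sqrt(info), abs=0.02)


class TestPhenotype:
    def test_variance_near_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(10_000, 1))
        y = simulate_phenotype(x, 0.001, rng)
        assert y.var() == pytest.approx(1.0, abs=0.05)

    def test_empty_causal_set_standard_normal(self):
        rng = np.random.default_rng(11)
        y = simulate_phenotype(np.empty((5000, 0)), 0.001, rng)
        assert y.mean() == pytest.approx(0.0, abs=0.05)
        assert y.var() == pytest.approx(1.0, abs=0.05)

    def test_excess_variance_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValidationError):
            simulate_phenotype(np.zeros((10, 3)), 0.4, rng)


class TestGWAS:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(13)
        n, p = 2000, 150
        x = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        st = run_gwas(x, y, "s")
        frac = np.mean(np.abs(st.z[st.present]) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.05)

    def test_degenerate_predictor_flagged(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(100, 2))
        x[:, 1] = 3.0
        st = run_gwas(x, rng.normal(size=100), "s")
        assert st.present.tolist() == [True, False]

    def test_slope_recovers_signal(self):
        rng = np.random.default_rng(15)
        n = 20_000
        x = rng.normal(size=(n, 1))
        y = 0.1 * x[:, 0] + rng.normal(scale=np.sqrt(1 - 0.01), size=n)
        st = run_gwas(x, y, "s")
        assert st.beta_hat[0] == pytest.approx(0.1, abs=0.03)


class TestMissingness:
    def _studies(self, p, d):
        return [make_study(f"s{u}", 100, np.zeros(p), np.full(p, 0.1))
                for u in range(d)]

    def test_none_rule_zero_frac_keeps_everything(self):
        rng = np.random.default_rng(16)
        out = inject_missingness(self._studies(10, 2), 0.0, [3], "none", rng)
        assert all(st.present.all() for st in out)

    def test_selected_count_matches_fraction(self):
        rng = np.random.default_rng(17)
        p = 100
        out = inject_missingness(self._studies(p, 3), 0.2, [5], "all_but_one", rng)
        present = np.stack([st.present for st in out])
        incomplete = ~present.all(axis=0)
        # 20 non-causal picks plus the causal variant
        assert incomplete.sum() == 21
        assert present.any(axis=0).all()  # nobody dropped entirely

    def test_causal_all_but_one(self):
        rng = np.random.default_rng(18)
        out = inject_missingness(self._studies(20, 4), 0.0, [2, 7], "all_but_one", rng)
        present = np.stack([st.present for st in out])
        assert present[:, 2].sum() == 1
        assert present[:, 7].sum() == 1


class TestMetaDataset:
    def test_deterministic_given_seed(self):
        sim = SimConfig(p=30, n_per_cohort=800, d=2, seed=19,
                        ld_spec=LDSpec(block_size=5))
        a, b = make_meta_dataset(sim), make_meta_dataset(sim)
        assert np.array_equal(a.meta.z, b.meta.z)
        assert np.array_equal(a.ld.r, b.ld.r)
        assert np.array_equal(a.truth.causal_set, b.truth.causal_set)
        assert np.array_equal(a.meta.presence, b.meta.presence)

    def test_causal_signal_dominates_region(self):
        hits = 0
        for seed in range(5):
            sim = SimConfig(p=40, n_per_cohort=10_000, d=2, seed=100 + seed,
                            ld_spec=LDSpec(block_size=8))
            data = make_meta_dataset(sim)
            zc = np.abs(data.meta.z[data.truth.causal_set[0]])
            hits += zc > np.median(np.abs(data.meta.z))
        assert hits == 5

    def test_complete_data_reduces_to_classic(self):
        """No missingness + INFO 1: the two likelihoods give the same PIPs."""
        sim = SimConfig(p=25, n_per_cohort=4000, d=2, missing_frac=0.0,
                        causal_missing_rule="none", info_range=(1.0, 1.0),
                        ld_spec=LDSpec(block_size=5), seed=20)
        data = make_meta_dataset(sim)
        kw = dict(kmax=2, seed=1, search="enumerate")
        miss = fine_map_meta(data.meta, data.ld, method="miss", **kw)
        classic = fine_map_meta(data.meta, data.ld, method="classic", **kw)
        # the overlap matrix is all-ones only up to sampling noise in the
        # per-study standard errors, so agreement is close but not exact
        assert np.max(np.abs(miss.pip - classic.pip)) < 0.01


def test_qc_filter_is_noop_on_generated_data():
    from finemapmiss.simulate import filter_panel
    sim = SimConfig(p=20, n_per_cohort=500, d=2, seed=21, ld_spec=LDSpec(block_size=4))
    data = make_meta_dataset(sim)
    mask = filter_panel(data.truth.maf, data.truth.realized_info)
    assert mask.all()
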