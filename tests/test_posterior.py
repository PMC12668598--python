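import numpy as np
import pytest
from scipy.special import logsumexp

from finemapmiss.bf import CausalConfig, LikelihoodModel, log_bf
from finemapmiss.io import LDMatrix, ValidationError
from finemapmiss.overlap import build_meta_covariance
from finemapmiss.posterior import (PriorSpec, compute_k_distribution, credible_sets,
                                   enumerate_posterior, log_prior, shotgun_search)
from tests.test_bf import random_model


def flat_model(z, n=10_000.0, tau2=0.0025):
    p = len(z)
    ld = LDMatrix(np.eye(p))
    om = build_meta_covariance(ld, np.ones((p, p)))
    return LikelihoodModel.from_meta(om, np.asarray(z, dtype=float),
                                     np.full(p, n), np.ones(p), ld, tau2=tau2)


class TestPrior:
    @pytest.mark.parametrize("p", [10, 1925])
    def test_one_causal_to_null_ratio(self, p):
        prior = PriorSpec(kmax=3, p=p)
        ratio = np.exp(log_prior((0,), prior) - log_prior((), prior))
        assert ratio == pytest.approx(1.0 / (p - 1), rel=1e-12)

    def test_beyond_kmax_is_minus_inf(self):
        prior = PriorSpec(kmax=2, p=10)
        assert log_prior((0, 1, 2), prior) == -np.inf

    def test_custom_per_k_weights(self):
        prior = PriorSpec(kmax=2, p=4, kind="custom_per_k", per_k=[1.0, 1.0, 0.0])
        assert np.isfinite(log_prior((0,), prior))
        assert log_prior((0, 1), prior) == -np.inf


class TestEnumerate:
    def test_null_data_gives_exchangeable_pips(self):
        model = flat_model(np.zeros(5))
        prior = PriorSpec(kmax=2, p=5)
        summary = enumerate_posterior(model, prior)
        np.testing.assert_allclose(summary.pip, summary.pip[0], atol=1e-12)
        assert summary.k_dist.sum() == pytest.approx(1.0, abs=1e-10)

    def test_two_variant_hand_normalization(self):
        # independent closed-form: BF_j = N(z_j; 0, 1+n tau2)/N(z_j; 0, 1)
        z, n, tau2 = np.array([3.0, 1.0]), 5000.0, 0.0025
        s2 = 1 + n * tau2
        lbf = -0.5 * np.log(s2) + 0.5 * z ** 2 * (1 - 1 / s2)
        prior = PriorSpec(kmax=1, p=2)
        lp0, lp1 = log_prior((), prior), log_prior((0,), prior)
        posts = np.array([lp0, lbf[0] + lp1, lbf[1] + lp1])
        want = np.exp(posts - logsumexp(posts))
        summary = enumerate_posterior(flat_model(z, n, tau2), prior)
        assert summary.pip[0] == pytest.approx(want[1], abs=1e-10)
        assert summary.pip[1] == pytest.approx(want[2], abs=1e-10)
        assert summary.k_dist[0] == pytest.approx(want[0], abs=1e-10)

    def test_penc_equals_pip_sum(self):
        rng = np.random.default_rng(0)
        model, _ = random_model(rng, 8)
        summary = enumerate_posterior(model, PriorSpec(kmax=3, p=8))
        assert summary.pip.sum() == pytest.approx(summary.penc, abs=1e-10)

    def test_cap_enforced(self):
        model = flat_model(np.zeros(30))
        with pytest.raises(ValidationError, match="shotgun"):
            enumerate_posterior(model, PriorSpec(kmax=3, p=30), cap=100)


class TestShotgunSearch:
    def test_one_iteration_from_null_scores_all_singles(self):
        rng = np.random.default_rng(1)
        model, _ = random_model(rng, 7)
        summary = shotgun_search(model, PriorSpec(kmax=3, p=7), iters=1, seed=0)
        assert set(summary.configs) == {()} | {(j,) for j in range(7)}

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        model, _ = random_model(rng, 10)
        prior = PriorSpec(kmax=3, p=10)
        s1 = shotgun_search(model, prior, iters=30, seed=7)
        s2 = shotgun_search(model, prior, iters=30, seed=7)
        assert np.array_equal(s1.pip, s2.pip)
        assert s1.configs.keys() == s2.configs.keys()

    def test_agrees_with_enumeration_on_small_problems(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            p = int(rng.integers(8, 15))
            model, _ = random_model(rng, p)
            prior = PriorSpec(kmax=2, p=p)
            exact = enumerate_posterior(model, prior)
            approx = shotgun_search(model, prior, iters=150, seed=11)
            assert np.max(np.abs(exact.pip - approx.pip)) <= 0.01


class TestKDistribution:
    def test_only_null_scored(self):
        prior = PriorSpec(kmax=2, p=5)
        k_dist = compute_k_distribution({(): 0.0}, prior)
        np.testing.assert_array_equal(k_dist, [1.0, 0.0, 0.0])

    def test_symmetric_split(self):
        prior = PriorSpec(kmax=1, p=2)
        k_dist = compute_k_distribution({(): 0.0, (0,): 2.0, (1,): 2.0}, prior)
        assert k_dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(4)
        model, _ = random_model(rng, 6)
        prior = PriorSpec(kmax=2, p=6)
        summary = enumerate_posterior(model, prior)
        scores = {cfg: v[0] for cfg, v in summary.configs.items()}
        np.testing.assert_allclose(compute_k_distribution(scores, prior),
                                   summary.k_dist, atol=1e-12)

    def test_requires_null(self):
        with pytest.raises(ValidationError):
            compute_k_distribution({(0,): 1.0}, PriorSpec(kmax=1, p=2))
        with pytest.raises(ValidationError):
            compute_k_distribution({}, PriorSpec(kmax=1, p=2))


class TestCredibleSets:
    def test_single_variant_region(self):
        model = flat_model(np.array([4.0]))
        prior = PriorSpec(kmax=1, p=1)
        summary = enumerate_posterior(model, prior)
        [cs] = credible_sets(model, prior, summary, k=1, theta=0.95)
        assert cs.members == [0]
        assert cs.member_probs[0] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_proxies_share_the_set(self):
        # r = 1 between two variants: b_bar = 0.5 each, both in the 95% set
        r = np.ones((2, 2))
        ld = LDMatrix(r)
        om = build_meta_covariance(ld, np.ones((2, 2)))
        model = LikelihoodModel.from_meta(om, np.array([5.0, 5.0]),
                                          np.full(2, 1e4), np.ones(2), ld)
        prior = PriorSpec(kmax=1, p=2)
        summary = enumerate_posterior(model, prior)
        [cs] = credible_sets(model, prior, summary, k=1, theta=0.95)
        assert sorted(cs.members) == [0, 1]
        np.testing.assert_allclose(cs.member_probs, 0.5, atol=1e-6)

    def test_matches_procedural_oracle(self):
        """Brute-force replay of the construction: score gamma_k - e_j + e_l
        for every replacement, normalize, take decreasing until > theta."""
        rng = np.random.default_rng(5)
        model, _ = random_model(rng, 5)
        prior = PriorSpec(kmax=2, p=5)
        summary = enumerate_posterior(model, prior)
        theta = 0.9
        sets = credible_sets(model, prior, summary, k=2, theta=theta)
        k_cfgs = {c: v[2] for c, v in summary.configs.items() if len(c) == 2}
        top = max(k_cfgs, key=k_cfgs.get)
        assert len(sets) == 2
        for cs, j in zip(sets, top):
            others = tuple(i for i in top if i != j)
            cands = [l for l in range(5) if l not in others]
            lbf = np.array([log_bf(CausalConfig(tuple(sorted(others + (l,)))), model)
                            for l in cands])
            b = np.exp(lbf - logsumexp(lbf))
            order = np.argsort(-b, kind="stable")
            cum, chosen = 0.0, []
            for i in order:
                chosen.append(cands[i])
                cum += b[i]
                if cum > theta:
                    break
            assert cs.anchor_variant == j
            assert set(cs.members) == set(chosen)
            assert cs.member_probs.sum() >= theta

    def test_missing_k_config_errors(self):
        model = flat_model(np.array([1.0, 0.5]))
        prior = PriorSpec(kmax=2, p=2)
        summary = shotgun_search(model, prior, iters=1, seed=0)  # only k <= 1 scored
        with pytest.raises(ValidationError, match="size 2"):
            credible_sets(model, prior, summary, k=2)
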