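"""Causal-inference observer: closed forms vs numerical integration, limits,
posterior behavior, strategies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from msimodels import (
    BCIParams,
    conditional_estimates,
    final_estimates,
    get_contract,
    likelihood_common,
    likelihood_independent,
    mle_estimate,
    posterior_common,
    run_model,
)

from conftest import av_pair


# --- independent numerical oracles ---------------------------------------


def oracle_likelihood_common(x_v, x_a, p):
    """Single numeric integral over the latent source position."""
    smax = max(p.sigma_a, p.sigma_v, p.sigma_p)
    lo = min(x_v, x_a, p.mu_p) - 12 * smax
    hi = max(x_v, x_a, p.mu_p) + 12 * smax
    val, _ = quad(
        lambda s: norm.pdf(x_v, s, p.sigma_v)
        * norm.pdf(x_a, s, p.sigma_a)
        * norm.pdf(s, p.mu_p, p.sigma_p),
        lo,
        hi,
        limit=500,
        points=[x_v, x_a, p.mu_p],
        epsabs=0,
        epsrel=1e-11,
    )
    return val


def oracle_likelihood_independent(x_v, x_a, p):
    """Two numeric marginal integrals (independent sources)."""
    smax = max(p.sigma_a, p.sigma_v, p.sigma_p)

    def marginal(x, sigma):
        lo, hi = min(x, p.mu_p) - 12 * smax, max(x, p.mu_p) + 12 * smax
        val, _ = quad(
            lambda s: norm.pdf(x, s, sigma) * norm.pdf(s, p.mu_p, p.sigma_p),
            lo,
            hi,
            limit=500,
            points=[x, p.mu_p],
            epsabs=0,
            epsrel=1e-11,
        )
        return val

    return marginal(x_v, p.sigma_v) * marginal(x_a, p.sigma_a)


def oracle_posterior(x_v, x_a, p):
    l1 = oracle_likelihood_common(x_v, x_a, p)
    l2 = oracle_likelihood_independent(x_v, x_a, p)
    return l1 * p.p_common / (l1 * p.p_common + l2 * (1 - p.p_common))


def random_params(rng):
    return BCIParams(
        p_common=rng.uniform(0.05, 0.95),
        sigma_a=rng.uniform(0.5, 10),
        sigma_v=rng.uniform(0.5, 10),
        sigma_p=rng.uniform(1, 30),
        mu_p=rng.uniform(-10, 10),
    )


UNIT = BCIParams(p_common=0.5, sigma_a=1.0, sigma_v=1.0, sigma_p=1.0, mu_p=0.0)


class TestLikelihoods:
    def test_common_reference_value(self):
        # frozen from the single-integral oracle at the origin
        assert likelihood_common(0.0, 0.0, UNIT) == pytest.approx(
            1 / (2 * math.pi * math.sqrt(3)), rel=1e-12
        )
        assert likelihood_common(0.0, 0.0, UNIT) == pytest.approx(
            oracle_likelihood_common(0.0, 0.0, UNIT), rel=1e-8
        )

    def test_independent_reference_value(self):
        assert likelihood_independent(0.0, 0.0, UNIT) == pytest.approx(
            1 / (4 * math.pi), rel=1e-12
        )
        assert likelihood_independent(0.0, 0.0, UNIT) == pytest.approx(
            oracle_likelihood_independent(0.0, 0.0, UNIT), rel=1e-8
        )

    def test_common_decreases_with_cue_conflict(self):
        vals = [likelihood_common(d / 2, -d / 2, UNIT) for d in (0.0, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_modality_swap_symmetry(self):
        p = BCIParams(0.5, sigma_a=2.0, sigma_v=5.0, sigma_p=10.0, mu_p=1.0)
        swapped = BCIParams(0.5, sigma_a=5.0, sigma_v=2.0, sigma_p=10.0, mu_p=1.0)
        assert likelihood_common(3.0, -4.0, p) == pytest.approx(
            likelihood_common(-4.0, 3.0, swapped), rel=1e-14
        )

    def test_independent_factorizes(self):
        p = UNIT
        # depends only on each cue's own marginal, not the conflict
        a = likelihood_independent(1.0, -1.0, p)
        b = likelihood_independent(1.0, 1.0, p) * (
            norm.pdf(-1.0, 0, math.sqrt(2)) / norm.pdf(1.0, 0, math.sqrt(2))
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_closed_forms_match_oracle_on_random_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = random_params(rng)
            x_v, x_a = rng.uniform(-20, 20, 2)
            assert likelihood_common(x_v, x_a, p) == pytest.approx(
                oracle_likelihood_common(x_v, x_a, p), rel=1e-6
            )
            assert likelihood_independent(x_v, x_a, p) == pytest.approx(
                oracle_likelihood_independent(x_v, x_a, p), rel=1e-6
            )


class TestPosterior:
    def test_prior_extremes_force_posterior(self):
        one = BCIParams(1.0, 1, 1, 1, 0)
        zero = BCIParams(0.0, 1, 1, 1, 0)
        for x in (0.0, 3.0, -17.0):
            assert posterior_common(x, -x, one) == 1.0
            assert posterior_common(x, -x, zero) == 0.0

    def test_reference_point_against_double_integration(self):
        # brute-force value of p(C=1 | 0, 0) for the unit generative model
        assert posterior_common(0.0, 0.0, UNIT) == pytest.approx(
            0.5358983848622454, rel=1e-10
        )
        assert posterior_common(0.0, 0.0, UNIT) == pytest.approx(
            oracle_posterior(0.0, 0.0, UNIT), rel=1e-8
        )

    @settings(derandomize=True, max_examples=40)
    @given(pc=st.floats(0.01, 0.99), d=st.floats(0.0, 15.0))
    def test_monotone_in_prior(self, pc, d):
        lo = BCIParams(pc * 0.5, 2.0, 3.0, 10.0, 0.0)
        hi = BCIParams(pc, 2.0, 3.0, 10.0, 0.0)
        assert posterior_common(d, -d, hi) >= posterior_common(d, -d, lo)

    def test_non_increasing_in_conflict_centered_prior(self):
        p = BCIParams(0.5, 2.0, 3.0, 10.0, 0.0)
        vals = [posterior_common(d / 2, -d / 2, p) for d in np.linspace(0, 30, 16)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestConditionalEstimates:
    def test_consensus_fixed_point(self):
        p = BCIParams(0.5, 2.0, 3.0, 5.0, 7.0)
        est = conditional_estimates(7.0, 7.0, p)
        assert est["fused"] == pytest.approx(7.0)
        assert est["seg_a"] == pytest.approx(7.0)

    def test_flat_prior_reduces_to_mle_fusion(self):
        p = BCIParams(0.5, 2.0, 1.0, 1e6, 0.0)
        est = conditional_estimates(10.0, 0.0, p)
        mle_fused, _ = mle_estimate(0.0, 10.0, 2.0, 1.0)
        assert est["fused"] == pytest.approx(mle_fused, abs=1e-5)

    def test_precision_weighted_example(self):
        p = BCIParams(0.5, 1.0, 1.0, 1.0, 0.0)
        est = conditional_estimates(12.0, 0.0, p)
        # (0 + 12 + 0) / 3 precisions of 1 each
        assert est["fused"] == pytest.approx(4.0)

    def test_fused_matches_numeric_posterior_mean(self):
        p = BCIParams(0.5, 2.0, 3.0, 8.0, 1.0)
        x_v, x_a = 6.0, -2.0
        num = quad(
            lambda s: s
            * norm.pdf(x_v, s, p.sigma_v)
            * norm.pdf(x_a, s, p.sigma_a)
            * norm.pdf(s, p.mu_p, p.sigma_p),
            -100,
            100,
            limit=400,
        )[0]
        den = quad(
            lambda s: norm.pdf(x_v, s, p.sigma_v)
            * norm.pdf(x_a, s, p.sigma_a)
            * norm.pdf(s, p.mu_p, p.sigma_p),
            -100,
            100,
            limit=400,
        )[0]
        assert conditional_estimates(x_v, x_a, p)["fused"] == pytest.approx(
            num / den, rel=1e-8
        )


class TestStrategies:
    def test_averaging_definition(self):
        p = BCIParams(0.5, 2.0, 3.0, 10.0, 0.0)
        out = final_estimates(6.0, -6.0, p)
        pi = out["posterior_common"]
        assert out["est_a"] == pytest.approx(
            pi * out["fused"] + (1 - pi) * out["seg_a"]
        )
        assert min(out["fused"], out["seg_a"]) <= out["est_a"] <= max(
            out["fused"], out["seg_a"]
        )

    def test_forced_fusion_at_prior_one(self):
        p = BCIParams(1.0, 2.0, 3.0, 10.0, 0.0)
        out = final_estimates(6.0, -6.0, p)
        assert out["est_a"] == out["fused"]
        assert out["est_v"] == out["fused"]

    def test_selection_picks_more_probable_structure(self):
        p_sel = BCIParams(0.9, 2.0, 3.0, 10.0, 0.0, strategy="selection")
        out = final_estimates(1.0, -1.0, p_sel)
        assert out["posterior_common"] > 0.5
        assert out["est_a"] == out["fused"]

    def test_matching_is_seeded(self):
        p_m = BCIParams(0.5, 2.0, 3.0, 10.0, 0.0, strategy="matching")
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        assert final_estimates(6.0, -6.0, p_m, rng1) == final_estimates(
            6.0, -6.0, p_m, rng2
        )


class TestRun:
    def test_causes_matches_posterior_oracle(self):
        stims = av_pair(pos_a=45, pos_v=39)
        params = {
            "p_common": 0.5,
            "auditory_sigma": 5.0,
            "visual_sigma": 5.0,
            "sigma_p": 5.0,
            "mu_p": 45.0,
        }
        r = run_model(get_contract("bci"), stims, params)
        p = BCIParams(0.5, 5.0, 5.0, 5.0, 45.0)
        assert r.causes == pytest.approx(oracle_posterior(39.0, 45.0, p), rel=1e-8)

    def test_temporal_dimension_runs_on_onsets(self):
        contract = get_contract("bci", dimension="time")
        stims = av_pair(pos_a=90, pos_v=90, onset_a=180, onset_v=160, duration=50)
        r = run_model(contract, stims)
        p = BCIParams(0.5, 50.0, 50.0, 150.0, 160.0)
        assert r.causes == pytest.approx(posterior_common(160.0, 180.0, p))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(Exception, match="strategy"):
            BCIParams(0.5, 1, 1, 1, 0, strategy="wishful")

    def test_noiseless_run_deterministic_without_seed(self):
        contract = get_contract("bci")
        r1 = run_model(contract, av_pair(), seed=None)
        r2 = run_model(contract, av_pair(), seed=None)
        assert np.array_equal(r1.activity.values, r2.activity.values)
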