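"""Transforms, posterior density, sampler contracts, R-hat and WAIC."""

import math

import numpy as np
import pytest

from fbl_rlddm.inference import (
    ModelSpec,
    _slice_update,
    log_posterior,
    prepare_cohort,
    rhat,
    sample_posterior,
    transform_params,
    untransform_params,
    waic,
)


class TestTransforms:
    def test_logit_center_maps_to_half(self):
        nat = transform_params(np.zeros(5))
        assert nat["eta_pos"] == 0.5 and nat["eta_neg"] == 0.5
        assert nat["a"] == 1.0 and nat["tau"] == 1.0

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x = rng.normal(0, 2, size=5)
            nat = transform_params(x)
            back = untransform_params(nat)
            names = ("a", "tau", "v_mod", "eta_pos", "eta_neg")
            np.testing.assert_allclose([back[n] for n in names], x, atol=1e-10)

    def test_tau_cap_bounds_tau(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            nat = transform_params(rng.normal(0, 3, size=5), tau_cap=0.8)
            assert 0.0 < nat["tau"] < 0.8


class TestLogPosterior:
    def test_single_and_dual_agree_when_rates_tied(self, small_cohort):
        log, _ = small_cohort
        packed, _ = prepare_cohort(log)
        single = ModelSpec("single_eta")
        dual = ModelSpec("dual_eta")
        rng = np.random.default_rng(3)
        for _ in range(5):
            mu4 = rng.normal(0, 0.5, 4)
            lsig4 = rng.normal(-1.5, 0.2, 4)
            z4 = rng.normal(0, 0.5, (len(packed), 4))
            vec_s = np.concatenate([mu4, lsig4, z4.ravel()])
            # duplicate the eta column for the dual variant
            mu5 = np.append(mu4, mu4[3])
            lsig5 = np.append(lsig4, lsig4[3])
            z5 = np.column_stack([z4, z4[:, 3]])
            vec_d = np.concatenate([mu5, lsig5, z5.ravel()])
            lp_s = log_posterior(single, packed, vec_s)
            lp_d = log_posterior(dual, packed, vec_d)
            # likelihood components identical; only the prior for the extra
            # group-level block differs, by its density at the tied values
            prior_extra = (-0.5 * (mu4[3] / 2.0) ** 2 - math.log(2.0)
                           - 0.5 * math.log(2 * math.pi))
            sig = math.exp(lsig4[3])
            prior_extra += (0.5 * math.log(2 / math.pi) - sig**2 / 2
                            + lsig4[3])
            prior_extra += float(-0.5 * np.sum(z4[:, 3] ** 2)
                                 - 0.5 * len(packed) * math.log(2 * math.pi))
            assert lp_d == pytest.approx(lp_s + prior_extra, rel=1e-9)

    def test_finite_at_generating_parameters(self, small_cohort):
        log, truth = small_cohort
        packed, subjects = prepare_cohort(log)
        spec = ModelSpec("dual_eta")
        mu = np.array([np.log(1.8), np.log(0.35), np.log(2.2), 0.0, -1.0])
        lsig = np.full(5, np.log(0.2))
        z = np.zeros((len(packed), 5))
        vec = np.concatenate([mu, lsig, z.ravel()])
        assert np.isfinite(log_posterior(spec, packed, vec))

    def test_infeasible_tau_gives_minus_inf(self, small_cohort):
        log, _ = small_cohort
        packed, _ = prepare_cohort(log)
        spec = ModelSpec("dual_eta")
        mu = np.array([0.0, np.log(5.0), 0.0, 0.0, 0.0])  # tau = 5 s >> RTs
        vec = np.concatenate([mu, np.full(5, -2.0), np.zeros(5 * len(packed))])
        assert log_posterior(spec, packed, vec) == -np.inf


class TestSliceSampler:
    def test_standard_normal_target_moments(self):
        rng = np.random.default_rng(42)
        logf = lambda x: -0.5 * x * x
        x, f = 0.0, 0.0
        draws = []
        for _ in range(6000):
            x, f, _ = _slice_update(x, f, logf, 1.0, rng)
            draws.append(x)
        draws = np.array(draws[500:])
        assert abs(draws.mean()) < 0.08
        assert abs(draws.var() - 1.0) < 0.12

    def test_conjugate_normal_posterior_recovered(self):
        """Normal likelihood with known sd + Normal prior: posterior mean and
        variance have closed forms; the slice chain must match them."""
        rng = np.random.default_rng(7)
        data = rng.normal(2.0, 1.0, size=25)
        prior_mu, prior_sd = 0.0, 3.0
        n, xbar = data.size, data.mean()
        post_prec = 1 / prior_sd**2 + n
        post_mean = (prior_mu / prior_sd**2 + n * xbar) / post_prec
        post_sd = 1 / np.sqrt(post_prec)

        logf = lambda m: (-0.5 * ((m - prior_mu) / prior_sd) ** 2
                          - 0.5 * np.sum((data - m) ** 2))
        x, f = 0.0, logf(0.0)
        draws = []
        for _ in range(8000):
            x, f, _ = _slice_update(x, f, logf, 0.5, rng)
            draws.append(x)
        draws = np.array(draws[1000:])
        mc_se = post_sd / np.sqrt(draws.size / 10)  # conservative ESS guess
        assert draws.mean() == pytest.approx(post_mean, abs=4 * mc_se)
        assert draws.std() == pytest.approx(post_sd, rel=0.15)


class TestSamplePosterior:
    def test_seed_fixed_double_run_identical(self, small_cohort):
        log, _ = small_cohort
        sub = log[log["subject"].isin([1, 2])]
        spec = ModelSpec("dual_eta")
        kw = dict(chains=2, iterations=40, warmup=20, rng_seed=5,
                  sweeps_per_iteration=1)
        d1 = sample_posterior(spec, sub, **kw)
        d2 = sample_posterior(spec, sub, **kw)
        for k in d1.group:
            np.testing.assert_array_equal(d1.group[k], d2.group[k])
        np.testing.assert_array_equal(d1.loglik, d2.loglik)

    def test_requested_chain_count_and_shapes(self, small_cohort):
        log, _ = small_cohort
        sub = log[log["subject"].isin([1, 2, 3])]
        draws = sample_posterior(ModelSpec("single_eta"), sub, chains=3,
                                 iterations=30, warmup=10, rng_seed=2,
                                 sweeps_per_iteration=1)
        assert draws.group["mu_a"].shape == (3, 20)
        assert draws.subject["eta"].shape == (3, 20, 3)
        n_resp = int((~sub["missing"]).sum())
        assert draws.loglik.shape == (3, 20, n_resp)

    def test_multi_task_log_rejected(self, small_cohort):
        import pandas as pd

        log, _ = small_cohort
        other = log.copy()
        other["task"] = "B"
        with pytest.raises(ValueError, match="separately"):
            prepare_cohort(pd.concat([log, other]))


class TestRhat:
    def test_identical_chains_give_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=200), (4, 1))
        assert rhat({"p": x})["p"] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_chains_converged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 1000))
        assert rhat({"p": x})["p"] < 1.01

    def test_agrees_with_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(2)
        # autocorrelated chains so R-hat is meaningfully above 1
        x = np.cumsum(rng.normal(size=(4, 500)), axis=1) * 0.05 \
            + rng.normal(size=(4, 500))
        ours = rhat({"p": x})["p"]
        theirs = float(az.rhat(az.convert_to_dataset(x[:, :, None]),
                               method="split").x.values[0])
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 500))
        x[0] += 5.0
        assert rhat({"p": x})["p"] > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat({"p": np.zeros((1, 100))})


class TestWaic:
    def test_degenerate_posterior(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (10, 1))
        lppd, p_waic, w = waic(ll)
        assert p_waic == pytest.approx(0.0, abs=1e-12)
        assert lppd == pytest.approx(-3.5)
        assert w == pytest.approx(7.0)

    def test_stable_over_700_nat_range(self):
        """log-mean-exp on a 3x3 toy matrix checked against 50-digit
        arithmetic (sympy)."""
        import sympy as sp

        ll = np.array([[-1000.0, -2.0, -0.3],
                       [-300.0, -2.5, -0.4],
                       [-1700.0, -1.5, -0.2]])
        lppd, p_waic, w = waic(ll)
        exp, log, R = sp.exp, sp.log, sp.Rational
        lppd_exact = sum(
            log(sum(exp(sp.Float(ll[s, i], 50)) for s in range(3)) / 3)
            for i in range(3))
        assert lppd == pytest.approx(float(lppd_exact.evalf(50)), rel=1e-10)
        assert np.isfinite(w)

    def test_matches_arviz_elpd_components(self, small_cohort):
        """WAIC pieces agree with the reference implementation on real draws."""
        import arviz as az

        log, _ = small_cohort
        sub = log[log["subject"].isin([1, 2])]
        draws = sample_posterior(ModelSpec("dual_eta"), sub, chains=2,
                                 iterations=60, warmup=30, rng_seed=8,
                                 sweeps_per_iteration=1)
        lppd, p_waic, w = waic(draws)
        idata = az.from_dict(
            log_likelihood={"obs": draws.loglik})
        ref = az.waic(idata, scale="deviance")
        assert w == pytest.approx(float(ref.elpd_waic), rel=0.01)
        assert p_waic == pytest.approx(float(ref.p_waic), rel=0.05)
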