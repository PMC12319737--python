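"""Hierarchical Bayesian estimation of the RLDDM and WAIC model comparison.

Model.  For each subject s and parameter p (a, tau, v_mod and one or two
learning rates), the unconstrained subject value is mu_p + sigma_p * z_sp
with z_sp ~ Normal(0, 1) (non-centered parameterization); link functions map
it to the natural scale.  Priors are weakly informative and overridable:
Normal(0, 2) on group means (unconstrained scale) and Half-Normal(1) on group
sds.  The likelihood chains the delta-rule association update with the WFPT
density of each responded trial.

Sampler.  Draws come from univariate slice sampling (stepping-out plus
shrinkage) applied coordinate-wise within a Gibbs scan, with per-coordinate
widths adapted during warmup.  After every scan an ancestral interweaving
move re-draws the group level conditionally on the *subject effects*
(mu conjugately, sigma by a cheap slice), which decorrelates the group mean
from the average subject offset — the slow direction of the non-centered
scan — without touching the likelihood.  Slice sampling needs no gradients
and never rejects, which suits the series-evaluated WFPT likelihood.

Diagnostics follow the usual practice: split-chain Gelman-Rubin R-hat per
parameter (convergence declared at max R-hat <= 1.01) and WAIC on the
deviance scale, -2 * (lppd - p_waic), where lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference_links import constrain, unconstrain
from .rlddm import PackedTrials, pack_trials, _seq_loglik_core

__all__ = [
    "ModelSpec",
    "FitConfig",
    "PosteriorDraws",
    "FitReport",
    "transform_params",
    "untransform_params",
    "log_posterior",
    "sample_posterior",
    "rhat",
    "waic",
    "fit_and_compare",
    "prepare_cohort",
]

_DUAL_PARAMS = ("a", "tau", "v_mod", "eta_pos", "eta_neg")
_SINGLE_PARAMS = ("a", "tau", "v_mod", "eta")


@dataclass
class ModelSpec:
    """Which RLDDM variant to fit, its links and prior hyperparameters."""

    variant: str = "dual_eta"  # or "single_eta" (ties eta_pos = eta_neg)
    prior_mu_mean: dict[str, float] = field(default_factory=dict)
    prior_mu_sd: dict[str, float] = field(default_factory=dict)
    prior_sigma_scale: dict[str, float] = field(default_factory=dict)
    tau_cap: float | None = None
    as0: float = 0.0
    reset_per_block: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("single_eta", "dual_eta"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _DUAL_PARAMS if self.variant == "dual_eta" else _SINGLE_PARAMS

    def mu_mean(self, name: str) -> float:
        return self.prior_mu_mean.get(name, 0.0)

    def mu_sd(self, name: str) -> float:
        return self.prior_mu_sd.get(name, 2.0)

    def sigma_scale(self, name: str) -> float:
        return self.prior_sigma_scale.get(name, 1.0)


@dataclass
class FitConfig:
    """Run lengths default to the full-scale protocol (4 chains of 10,000
    iterations, 4,000 warm-up); tests and desk-scale runs pass smaller
    values explicitly."""

    chains: int = 4
    iterations: int = 10_000
    warmup: int = 4_000
    rng_seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Post-warmup draws (chain, iteration) plus the per-trial loglik matrix."""

    param_names: tuple[str, ...]
    group: dict[str, np.ndarray]          # 'mu_a', 'sigma_a', ... -> (C, S)
    subject: dict[str, np.ndarray]        # natural scale, (C, S, N)
    loglik: np.ndarray                    # (C, S, n_responded_trials)
    n_subjects: int
    config: FitConfig

    @property
    def n_chains(self) -> int:
        return self.loglik.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Group-level draws in long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.group.items():
            c, s = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(1, c + 1), s),
                "iteration": np.tile(np.arange(1, s + 1), c),
                "parameter": name,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def group_means_natural(self) -> pd.DataFrame:
        """Posterior mean and 80% credibility interval of link-transformed
        group means, one row per parameter."""
        rows = []
        for name in self.param_names:
            draws = constrain(name, self.group[f"mu_{name}"]).ravel()
            lo, hi = np.percentile(draws, [10, 90])
            rows.append({"parameter": name, "mean": draws.mean(),
                         "ci10": lo, "ci90": hi})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transforms

def transform_params(unconstrained: dict[str, float] | np.ndarray,
                     param_names: tuple[str, ...] = _DUAL_PARAMS,
                     tau_cap: float | None = None) -> dict[str, float]:
    """Unconstrained vector/dict -> natural-scale parameter dict."""
    if not isinstance(unconstrained, dict):
        unconstrained = dict(zip(param_names, np.asarray(unconstrained)))
    return {name: float(constrain(name, x, tau_cap if name == "tau" else None))
            for name, x in unconstrained.items()}


def untransform_params(natural: dict[str, float],
                       tau_cap: float | None = None) -> dict[str, float]:
    return {name: float(unconstrain(name, v, tau_cap if name == "tau" else None))
            for name, v in natural.items()}


# ---------------------------------------------------------------------------
# data preparation

def prepare_cohort(log: pd.DataFrame, reset_per_block: bool = True,
                   ) -> tuple[list[PackedTrials], list]:
    """Split a cohort event log into per-subject packed trial arrays.

    Fits are per task (as in the analysis design); a log spanning several
    tasks must be filtered first.
    """
    if "task" in log and log["task"].nunique() > 1:
        raise ValueError("cohort log spans multiple tasks; fit each task "
                         "separately (filter by the 'task' column)")
    subjects = sorted(log["subject"].unique())
    packed = [pack_trials(log[log["subject"] == s], reset_per_block)
              for s in subjects]
    return packed, subjects


# ---------------------------------------------------------------------------
# posterior density

def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return (0.5 * math.log(2.0 / math.pi) - math.log(scale)
            - x * x / (2.0 * scale * scale))


def _subject_natural(spec: ModelSpec, mu: np.ndarray, sigma: np.ndarray,
                     z_row: np.ndarray) -> tuple[float, float, float, float, float]:
    names = spec.param_names
    vals = {}
    for j, name in enumerate(names):
        vals[name] = float(constrain(name, mu[j] + sigma[j] * z_row[j],
                                     spec.tau_cap if name == "tau" else None))
    if spec.variant == "single_eta":
        return vals["a"], vals["tau"], vals["v_mod"], vals["eta"], vals["eta"]
    return (vals["a"], vals["tau"], vals["v_mod"],
            vals["eta_pos"], vals["eta_neg"])


def _subject_ll(spec: ModelSpec, packed: PackedTrials, mu, sigma, z_row) -> float:
    a, tau, v_mod, ep, en = _subject_natural(spec, mu, sigma, z_row)
    total, *_ = _seq_loglik_core(a, tau, v_mod, ep, en, 0.5,
                                 packed.sound, packed.is_match, packed.missing,
                                 packed.correct, packed.rt_s,
                                 packed.block_start, spec.as0)
    return total


def log_posterior(spec: ModelSpec, packed: list[PackedTrials],
                  vector: np.ndarray) -> float:
    """Joint log posterior density at an unconstrained vector.

    Layout: [mu (P), log_sigma (P), z (N*P row-major)] with P parameters and
    N subjects.  Includes the log-Jacobian of the log-sigma parameterization.
    """
    P = len(spec.param_names)
    N = len(packed)
    mu = vector[:P]
    lsig = vector[P:2 * P]
    z = vector[2 * P:].reshape(N, P)
    sigma = np.exp(lsig)
    lp = 0.0
    for j, name in enumerate(spec.param_names):
        m0, s0 = spec.mu_mean(name), spec.mu_sd(name)
        lp += -0.5 * ((mu[j] - m0) / s0) ** 2 - math.log(s0) - 0.5 * math.log(2 * math.pi)
        lp += _halfnormal_logpdf(sigma[j], spec.sigma_scale(name)) + lsig[j]
    lp += float(-0.5 * np.sum(z * z) - 0.5 * N * P * math.log(2 * math.pi))
    if not np.isfinite(lp):
        return -np.inf
    for i in range(N):
        lp += _subject_ll(spec, packed[i], mu, sigma, z[i])
        if not np.isfinite(lp):
            return -np.inf
    return float(lp)


# ---------------------------------------------------------------------------
# slice sampler

def _slice_update(x0, f0, logf, w, rng, max_step=25):
    """One univariate slice-sampling update (Neal 2003).

    ``logf`` returns the log target; returns (x1, f1, interval_width_used).
    """
    y = f0 - rng.exponential()
    u = rng.uniform()
    L = x0 - w * u
    R = L + w
    for _ in range(max_step):
        if logf(L) <= y:
            break
        L -= w
    for _ in range(max_step):
        if logf(R) <= y:
            break
        R += w
    while True:
        x1 = rng.uniform(L, R)
        f1 = logf(x1)
        if f1 > y:
            return x1, f1, abs(x1 - x0)
        if x1 < x0:
            L = x1
        else:
            R = x1


class _GibbsState:
    """Mutable chain state with cached per-subject log likelihoods."""

    def __init__(self, spec: ModelSpec, packed: list[PackedTrials],
                 rng: np.random.Generator, min_rt: float):
        self.spec = spec
        self.packed = packed
        P = len(spec.param_names)
        N = len(packed)
        mu0 = {"a": math.log(1.5), "tau": math.log(min(0.25, 0.5 * min_rt)),
               "v_mod": 0.0, "eta": 0.0, "eta_pos": 0.0, "eta_neg": 0.0}
        self.mu = np.array([mu0[n] for n in spec.param_names]) + rng.normal(0, 0.15, P)
        self.lsig = np.full(P, math.log(0.2)) + rng.normal(0, 0.1, P)
        self.z = rng.normal(0, 0.2, size=(N, P))
        self.subj_ll = np.array([
            _subject_ll(spec, packed[i], self.mu, np.exp(self.lsig), self.z[i])
            for i in range(N)
        ])
        if not np.all(np.isfinite(self.subj_ll)):
            raise RuntimeError("infeasible initialization (check RTs vs tau)")
        # slice widths, adapted during warmup
        self.w_mu = np.full(P, 0.4)
        self.w_lsig = np.full(P, 0.4)
        self.w_z = np.full((N, P), 0.8)
        self.w_dir = 0.3
        # running moments for covariance-adapted direction moves
        self._g_count = 0
        self._g_mean = np.zeros(2 * P)
        self._g_m2 = np.zeros((2 * P, 2 * P))
        self._z_count = 0
        self._z_mean = np.zeros((N, P))
        self._z_m2 = np.zeros((N, P, P))

    def record_stats(self) -> None:
        g = np.concatenate([self.mu, self.lsig])
        self._g_count += 1
        delta = g - self._g_mean
        self._g_mean += delta / self._g_count
        self._g_m2 += np.outer(delta, g - self._g_mean)
        self._z_count += 1
        dz = self.z - self._z_mean
        self._z_mean += dz / self._z_count
        self._z_m2 += np.einsum("ij,ik->ijk", dz, self.z - self._z_mean)

    def update_subject_direction(self, i: int, rng) -> None:
        """Slice move along a covariance-adapted direction of subject i's z row.

        Coordinate updates random-walk slowly along within-subject parameter
        trade-offs (e.g. drift scaling vs learning rate); this move travels
        them directly at the cost of one subject likelihood per evaluation.
        """
        spec = self.spec
        P = len(spec.param_names)
        if self._z_count > 50:
            cov = self._z_m2[i] / (self._z_count - 1) + 1e-8 * np.eye(P)
            u = np.linalg.cholesky(cov) @ rng.normal(size=P)
            w = 2.0
        else:
            u = rng.normal(size=P)
            u /= np.linalg.norm(u)
            w = 1.0
        sigma = np.exp(self.lsig)
        z0 = self.z[i].copy()
        cache = {"ll": None}

        def logf(t):
            zr = z0 + t * u
            ll = _subject_ll(spec, self.packed[i], self.mu, sigma, zr)
            cache["ll"] = ll
            return -0.5 * float(zr @ zr) + ll

        f0 = -0.5 * float(z0 @ z0) + self.subj_ll[i]
        t1, f1, _ = _slice_update(0.0, f0, logf, w, rng)
        self.z[i] = z0 + t1 * u
        self.subj_ll[i] = f1 + 0.5 * float(self.z[i] @ self.z[i])

    # -- coordinate updates ------------------------------------------------
    def update_group_coord(self, which: str, j: int, rng, adapt: bool):
        spec, packed = self.spec, self.packed
        name = spec.param_names[j]
        N = len(packed)
        cand_ll = np.empty(N)
        last = {"x": None}

        def logf(x):
            mu, lsig = self.mu.copy(), self.lsig.copy()
            if which == "mu":
                mu[j] = x
                prior = -0.5 * ((x - spec.mu_mean(name)) / spec.mu_sd(name)) ** 2
            else:
                lsig[j] = x
                prior = _halfnormal_logpdf(math.exp(x), spec.sigma_scale(name)) + x
            if not np.isfinite(prior):
                return -np.inf
            sigma = np.exp(lsig)
            tot = prior
            for i in range(N):
                cand_ll[i] = _subject_ll(spec, packed[i], mu, sigma, self.z[i])
                tot += cand_ll[i]
                if not np.isfinite(tot):
                    return -np.inf
            last["x"] = x
            return tot

        arr = self.mu if which == "mu" else self.lsig
        warr = self.w_mu if which == "mu" else self.w_lsig
        x0 = arr[j]
        if which == "mu":
            f0 = -0.5 * ((x0 - spec.mu_mean(name)) / spec.mu_sd(name)) ** 2 \
                 + self.subj_ll.sum()
        else:
            f0 = _halfnormal_logpdf(math.exp(x0), spec.sigma_scale(name)) + x0 \
                 + self.subj_ll.sum()
        x1, _, dx = _slice_update(x0, f0, logf, warr[j], rng)
        arr[j] = x1
        if last["x"] == x1:
            self.subj_ll[:] = cand_ll
        else:  # accepted point differs from last cache (finite->-inf edge)
            sigma = np.exp(self.lsig)
            self.subj_ll[:] = [
                _subject_ll(spec, packed[i], self.mu, sigma, self.z[i])
                for i in range(N)
            ]
        if adapt:
            warr[j] = min(4.0, max(0.05, 0.7 * warr[j] + 0.9 * dx))

    def update_subject_coord(self, i: int, j: int, rng, adapt: bool):
        spec = self.spec
        sigma = np.exp(self.lsig)
        z_row = self.z[i].copy()
        cache = {"ll": None}

        def logf(x):
            z_row[j] = x
            ll = _subject_ll(spec, self.packed[i], self.mu, sigma, z_row)
            cache["ll"] = ll
            return -0.5 * x * x + ll

        x0 = self.z[i, j]
        f0 = -0.5 * x0 * x0 + self.subj_ll[i]
        x1, f1, dx = _slice_update(x0, f0, logf, self.w_z[i, j], rng)
        self.z[i, j] = x1
        self.subj_ll[i] = f1 + 0.5 * x1 * x1
        if adapt:
            self.w_z[i, j] = min(6.0, max(0.05, 0.7 * self.w_z[i, j] + 0.9 * dx))

    def update_group_direction(self, rng, adapt: bool):
        """Slice update along a random direction in joint (mu, log sigma) space.

        Coordinate-wise scans stall on correlated group-level directions
        (e.g. drift scaling vs learning-rate means, which trade off in the
        likelihood); an isotropic random-direction move costs the same per
        evaluation but travels along them.
        """
        spec, packed = self.spec, self.packed
        P = len(spec.param_names)
        N = len(packed)
        if self._g_count > 50:
            # direction from the estimated group covariance: its norm carries
            # the posterior scale along that direction, so a unit slice width
            # suffices regardless of axis
            cov = self._g_m2 / (self._g_count - 1) + 1e-8 * np.eye(2 * P)
            u = np.linalg.cholesky(cov) @ rng.normal(size=2 * P)
            w = 2.0
        else:
            u = rng.normal(size=2 * P)
            u /= np.linalg.norm(u)
            w = self.w_dir
        cand_ll = np.empty(N)
        last = {"t": None}

        def prior_at(mu, lsig):
            lp = 0.0
            for j, name in enumerate(spec.param_names):
                lp += -0.5 * ((mu[j] - spec.mu_mean(name)) / spec.mu_sd(name)) ** 2
                lp += _halfnormal_logpdf(math.exp(lsig[j]),
                                         spec.sigma_scale(name)) + lsig[j]
            return lp

        def logf(t):
            mu = self.mu + t * u[:P]
            lsig = self.lsig + t * u[P:]
            lp = prior_at(mu, lsig)
            if not np.isfinite(lp):
                return -np.inf
            sigma = np.exp(lsig)
            for i in range(N):
                cand_ll[i] = _subject_ll(spec, packed[i], mu, sigma, self.z[i])
                lp += cand_ll[i]
                if not np.isfinite(lp):
                    return -np.inf
            last["t"] = t
            return lp

        f0 = prior_at(self.mu, self.lsig) + self.subj_ll.sum()
        t1, _, dt = _slice_update(0.0, f0, logf, w, rng)
        self.mu = self.mu + t1 * u[:P]
        self.lsig = self.lsig + t1 * u[P:]
        if last["t"] == t1:
            self.subj_ll[:] = cand_ll
        else:
            sigma = np.exp(self.lsig)
            self.subj_ll[:] = [
                _subject_ll(spec, packed[i], self.mu, sigma, self.z[i])
                for i in range(N)
            ]
        if adapt and self._g_count <= 50:
            self.w_dir = min(2.0, max(0.02, 0.7 * self.w_dir + 0.9 * dt))

    def interweave(self, rng):
        """Re-draw (mu, sigma) given the subject *effects* e = mu + sigma z.

        The likelihood depends only on e, so this move costs no likelihood
        evaluations; it is the centered half of an interweaving pair and
        breaks the mu <-> mean(z) random walk of the non-centered scan.
        """
        spec = self.spec
        N = len(self.packed)
        for j, name in enumerate(spec.param_names):
            sig = math.exp(self.lsig[j])
            e = self.mu[j] + sig * self.z[:, j]
            # conjugate Normal draw for mu_j | e, sigma_j
            m0, s0 = spec.mu_mean(name), spec.mu_sd(name)
            prec = 1.0 / s0**2 + N / sig**2
            mean = (m0 / s0**2 + e.sum() / sig**2) / prec
            self.mu[j] = rng.normal(mean, 1.0 / math.sqrt(prec))
            # slice draw for log sigma_j | e, mu_j (cheap: closed-form target)
            resid2 = float(np.sum((e - self.mu[j]) ** 2))
            scale = spec.sigma_scale(name)

            def logf(ls):
                s = math.exp(ls)
                return (_halfnormal_logpdf(s, scale) + ls
                        - N * ls - resid2 / (2.0 * s * s))

            ls0 = self.lsig[j]
            self.lsig[j], _, _ = _slice_update(ls0, logf(ls0), logf, 0.5, rng)
            self.z[:, j] = (e - self.mu[j]) / math.exp(self.lsig[j])


def _run_chain(spec: ModelSpec, packed: list[PackedTrials], iterations: int,
               warmup: int, seed: int, min_rt: float, sweeps: int = 3):
    rng = np.random.default_rng(seed)
    state = _GibbsState(spec, packed, rng, min_rt)
    P = len(spec.param_names)
    N = len(packed)
    keep = iterations - warmup
    mu_out = np.empty((keep, P))
    sig_out = np.empty((keep, P))
    theta_out = np.empty((keep, N, P))
    resp_mask = np.concatenate([~p.missing for p in packed])
    ll_out = np.empty((keep, int(resp_mask.sum())))
    for it in range(iterations):
        adapt = it < warmup
        # one iteration applies the composed kernel `sweeps` times; each
        # sweep is a full Gibbs scan plus the direction and interweaving moves
        for _ in range(sweeps):
            for j in range(P):
                state.update_group_coord("mu", j, rng, adapt)
                state.update_group_coord("lsig", j, rng, adapt)
            for i in range(N):
                for j in range(P):
                    state.update_subject_coord(i, j, rng, adapt)
                for _ in range(4):
                    state.update_subject_direction(i, rng)
            for _ in range(2):
                state.update_group_direction(rng, adapt)
            state.interweave(rng)
            state.record_stats()
        if it >= warmup:
            k = it - warmup
            mu_out[k] = state.mu
            sig_out[k] = np.exp(state.lsig)
            sigma = np.exp(state.lsig)
            lls = []
            for i in range(N):
                nat = _subject_natural(spec, state.mu, sigma, state.z[i])
                theta_out[k, i] = nat[:P]  # single_eta: 4th entry is the tied eta
                _, ll, *_ = _seq_loglik_core(
                    nat[0], nat[1], nat[2], nat[3], nat[4], 0.5,
                    packed[i].sound, packed[i].is_match, packed[i].missing,
                    packed[i].correct, packed[i].rt_s, packed[i].block_start,
                    spec.as0)
                lls.append(ll[~packed[i].missing])
            ll_out[k] = np.concatenate(lls)
    return mu_out, sig_out, theta_out, ll_out


def sample_posterior(spec: ModelSpec, data: pd.DataFrame | list[PackedTrials],
                     chains: int = 4, iterations: int = 10_000,
                     warmup: int = 4_000, rng_seed: int = 0,
                     sweeps_per_iteration: int = 3) -> PosteriorDraws:
    """Draw from the hierarchical posterior; reproducible under a fixed seed.

    One iteration applies ``sweeps_per_iteration`` composed Gibbs sweeps (a
    stronger transition kernel, the way gradient samplers compose many
    integrator steps per iteration); draws are recorded per iteration.
    """
    if isinstance(data, pd.DataFrame):
        packed, _ = prepare_cohort(data, spec.reset_per_block)
    else:
        packed = data
    rts = np.concatenate([p.rt_s[~p.missing] for p in packed])
    min_rt = float(np.min(rts)) if rts.size else 1.0
    cfg = FitConfig(chains=chains, iterations=iterations, warmup=warmup,
                    rng_seed=rng_seed)
    seeds = np.random.SeedSequence(rng_seed).generate_state(chains) % (2**31)
    results = [_run_chain(spec, packed, iterations, warmup, int(s), min_rt,
                          sweeps=sweeps_per_iteration)
               for s in seeds]
    P = len(spec.param_names)
    group: dict[str, np.ndarray] = {}
    for j, name in enumerate(spec.param_names):
        group[f"mu_{name}"] = np.stack([r[0][:, j] for r in results])
        group[f"sigma_{name}"] = np.stack([r[1][:, j] for r in results])
    subject = {name: np.stack([r[2][:, :, j] for r in results])
               for j, name in enumerate(spec.param_names)}
    loglik = np.stack([r[3] for r in results])
    return PosteriorDraws(spec.param_names, group, subject, loglik,
                          n_subjects=len(packed), config=cfg)


# ---------------------------------------------------------------------------
# diagnostics

def _split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for draws shaped (chains, draws)."""
    c, n = x.shape
    if c < 2:
        raise ValueError("split R-hat needs at least two chains")
    half = n // 2
    seqs = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, nn = seqs.shape
    W = float(seqs.var(axis=1, ddof=1).mean())
    B = nn * float(seqs.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0  # identical chains (degenerate but converged)
    var_hat = (nn - 1) / nn * W + B / nn
    # the estimator can dip slightly below 1 by finite-sample noise; floor it
    return max(1.0, float(math.sqrt(var_hat / W)))


def rhat(draws: PosteriorDraws | dict[str, np.ndarray],
         include_subject: bool = False) -> dict[str, float]:
    """Per-parameter split R-hat; group level by default."""
    if isinstance(draws, dict):
        return {name: _split_rhat(arr) for name, arr in draws.items()}
    out = {name: _split_rhat(arr) for name, arr in draws.group.items()}
    if include_subject:
        for name, arr in draws.subject.items():
            for i in range(arr.shape[2]):
                out[f"{name}[{i + 1}]"] = _split_rhat(arr[:, :, i])
    return out


def waic(draws: PosteriorDraws | np.ndarray) -> tuple[float, float, float]:
    """(lppd, p_waic, waic) from the per-trial log-likelihood matrix.

    lppd uses a stable log-mean-exp over draws; p_waic is the summed
    per-trial variance of the log likelihood; waic = -2 (lppd - p_waic),
    lower is better.
    """
    ll = draws if isinstance(draws, np.ndarray) else \
        draws.loglik.reshape(-1, draws.loglik.shape[-1])
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(S)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1))) if S > 1 else 0.0
    return lppd, p_waic, -2.0 * (lppd - p_waic)


@dataclass
class FitReport:
    variant: str
    rhat: dict[str, float]
    max_rhat: float
    ess: dict[str, float]
    lppd: float
    p_waic: float
    waic: float
    converged: bool
    summary: pd.DataFrame
    subject_means: pd.DataFrame
    draws: "PosteriorDraws | None" = None


def _make_report(spec: ModelSpec, draws: PosteriorDraws,
                 threshold: float) -> FitReport:
    import arviz as az

    rh = rhat(draws)
    max_rhat = max(rh.values())
    ess = {name: float(az.ess(arr[None] if arr.ndim == 1 else arr))
           for name, arr in draws.group.items()}
    lppd, p_waic, w = waic(draws)
    rows = []
    for name, arr in draws.group.items():
        flat = arr.ravel()
        lo, hi = np.percentile(flat, [10, 90])
        rows.append({"parameter": name, "mean": flat.mean(), "sd": flat.std(),
                     "ci10": lo, "ci90": hi, "rhat": rh[name]})
    subj_rows = []
    for name, arr in draws.subject.items():
        means = arr.mean(axis=(0, 1))
        for i, m in enumerate(means, start=1):
            subj_rows.append({"subject": i, "parameter": name, "post_mean": m})
    return FitReport(spec.variant, rh, max_rhat, ess, lppd, p_waic, w,
                     max_rhat <= threshold, pd.DataFrame(rows),
                     pd.DataFrame(subj_rows), draws=draws)


def fit_and_compare(data: pd.DataFrame, specs: list[ModelSpec],
                    config: FitConfig | None = None,
                    ) -> tuple[dict[str, FitReport], pd.DataFrame]:
    """Fit each model variant and rank them by WAIC (lower is better)."""
    if not specs:
        raise ValueError("need at least one model spec")
    config = config or FitConfig()
    reports: dict[str, FitReport] = {}
    for spec in specs:
        draws = sample_posterior(spec, data, chains=config.chains,
                                 iterations=config.iterations,
                                 warmup=config.warmup,
                                 rng_seed=config.rng_seed)
        reports[spec.variant] = _make_report(spec, draws,
                                             config.rhat_threshold)
    table = pd.DataFrame([
        {"variant": name, "waic": rep.waic, "lppd": rep.lppd,
         "p_waic": rep.p_waic, "max_rhat": rep.max_rhat,
         "converged": rep.converged}
        for name, rep in reports.items()
    ]).sort_values("waic").reset_index(drop=True)
    return reports, table
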