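"""Wiener first-passage-time (WFPT) density for the two-boundary diffusion model.

The density of hitting the *lower* boundary at decision time ``u`` (drift ``v``,
boundary separation ``a``, relative start ``w`` measured from the lower
boundary) factors into an exponential prefactor and a standardized series in
``u' = u / a**2``:

    f(u) = (1/a^2) * exp(-v*a*w - v^2*u/2) * f1(u', w)

where ``f1`` admits two complementary expansions — a small-time sum over image
charges and a large-time Fourier sine series.  Following the usual numerical
treatment, the expansion needing fewer terms for a requested absolute error is
selected per evaluation; the prefactor is kept in log space so long RTs and
large drifts do not underflow.  The upper-boundary density is obtained by the
reflection v -> -v, w -> 1 - w.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, prange

__all__ = [
    "wfpt_logpdf",
    "wfpt_pdf",
    "choice_probability",
    "wfpt_logpdf_array",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _f1_lower(u_norm: float, w: float, err: float) -> float:
    """Standardized lower-boundary density at normalized time u' = u/a^2."""
    # number of terms required by each expansion (absolute error <= err)
    if math.pi * u_norm * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u_norm * err) / (math.pi**2 * u_norm))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u_norm)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u_norm))
    if 2.0 * _SQRT_2PI * u_norm * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u_norm * math.log(2.0 * _SQRT_2PI * u_norm * err))
        ks = max(ks, math.sqrt(u_norm) + 1.0)
    else:
        ks = 2.0

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        acc = 0.0
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            acc += wk * math.exp(-(wk * wk) / (2.0 * u_norm))
        return acc / math.sqrt(2.0 * math.pi * u_norm**3)
    # large-time expansion
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-(k * k) * math.pi**2 * u_norm / 2.0) * math.sin(
            k * math.pi * w
        )
    return math.pi * acc


@njit(cache=True)
def wfpt_logpdf(t: float, upper: bool, a: float, v: float, w: float, tau: float,
                err: float = 1e-7) -> float:
    """Log density of responding at the given boundary at time ``t``.

    ``t`` is the full response time; decision time is ``t - tau``.  Returns
    -inf for infeasible times (t <= tau) so callers can treat such trials as
    zero-likelihood rather than raising inside tight loops.
    """
    if not (math.isfinite(a) and math.isfinite(v) and math.isfinite(tau)
            and math.isfinite(t)):
        return -np.inf
    if a <= 1e-6 or w <= 0.0 or w >= 1.0:
        # a near machine zero: all mass is absorbed at u ~ 0, density ~ 0
        # for any observable RT (and a*a would underflow below)
        return -np.inf
    u = t - tau
    if u <= 0.0:
        return -np.inf
    vv = v
    ww = w
    if upper:
        vv = -v
        ww = 1.0 - w
    u_norm = u / (a * a)
    if u_norm < 1e-12:  # extreme boundary separation: negligible density
        return -np.inf
    f1 = _f1_lower(u_norm, ww, err)
    if f1 <= 0.0:
        # series round-off in the extreme tails; density is effectively zero
        return -np.inf
    return math.log(f1) - vv * a * ww - vv * vv * u / 2.0 - 2.0 * math.log(a)


@njit(cache=True)
def wfpt_pdf(t: float, upper: bool, a: float, v: float, w: float, tau: float,
             err: float = 1e-7) -> float:
    lp = wfpt_logpdf(t, upper, a, v, w, tau, err)
    if lp == -np.inf:
        return 0.0
    return math.exp(lp)


@njit(cache=True, parallel=False)
def wfpt_logpdf_array(t: np.ndarray, upper: np.ndarray, a: float, v: float,
                      w: float, tau: float, err: float = 1e-7) -> np.ndarray:
    out = np.empty(t.shape[0])
    for i in prange(t.shape[0]):
        out[i] = wfpt_logpdf(t[i], bool(upper[i]), a, v, w, tau, err)
    return out


@njit(cache=True)
def choice_probability(a: float, v: float, w: float) -> float:
    """Probability of absorption at the upper boundary (gambler's ruin form).

    p_upper = (1 - exp(-2 v a w)) / (1 - exp(-2 v a)); reduces to w at v = 0.
    """
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return w
    return math.expm1(-x * w) / math.expm1(-x)
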