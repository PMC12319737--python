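"""Link functions between unconstrained and natural parameter scales.

a and v_mod are strictly positive (exp link); eta_pos/eta_neg live in [0, 1]
(inverse-logit link); tau is positive (exp link) or, when a cap is supplied
(e.g. the subject's minimum RT), a scaled inverse-logit bounded by the cap.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["constrain", "unconstrain", "LINKS"]

LINKS = {
    "a": "exp",
    "tau": "exp",
    "v_mod": "exp",
    "eta_pos": "logit",
    "eta_neg": "logit",
    "eta": "logit",
}


def constrain(name: str, x, tau_cap: float | None = None):
    """Map an unconstrained value to the parameter's natural scale."""
    link = LINKS[name]
    if name == "tau" and tau_cap is not None:
        return tau_cap * expit(x)
    if link == "exp":
        return np.exp(x)
    return expit(x)


def unconstrain(name: str, value, tau_cap: float | None = None):
    """Inverse of :func:`constrain` (round-trips to ~1e-10)."""
    link = LINKS[name]
    if name == "tau" and tau_cap is not None:
        return logit(np.asarray(value) / tau_cap)
    if link == "exp":
        return np.log(value)
    return logit(value)
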