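"""Confirmatory-trial sizing and Dunnett-type critical values.

All effects are standardized (sigma = 1).  A single-stage two-arm
confirmatory trial with n2 patients per arm rejects at one-sided level
alpha when Z = (Ybar_T - Ybar_C) / sqrt(2/n2) > z_{1-alpha}; its power at
true standardized effect mu is

    R(mu) = Phi( mu * sqrt(n2/2) - z_{1-alpha} ).

Multi-arm confirmatory trials (i experimental arms sharing one control,
equal allocation) control the family-wise error rate with a Dunnett-type
critical value: the i z-statistics are equicorrelated standard normal with
pairwise correlation 1/2 under the global null, and c2(i) solves
P(max Z > c2) = alpha.  Per-arm sample size is set so the marginal power
of a prespecified arm with effect delta equals 1 - beta.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize
from scipy.special import ndtr
from scipy.stats import norm

from .types import ConfirmatoryDesign, ConfirmatorySpec

__all__ = [
    "phase3_power_function",
    "single_stage_n2",
    "dunnett_c2",
    "multiarm_n2",
    "multiarm_design",
]

# critical values to 1e-8 on the z scale (design decision)
_C2_XTOL = 1e-10


def phase3_power_function(mu, n2: float, alpha: float):
    """Probability R(mu) that a two-arm confirmatory trial rejects.

    Parameters
    ----------
    mu : true standardized treatment effect (array-like ok).
    n2 : per-arm sample size (> 0, need not be integer).
    alpha : one-sided type-I error rate.
    """
    if n2 <= 0:
        raise ValueError(f"n2 must be > 0, got {n2}")
    mu = np.asarray(mu, dtype=float)
    out = ndtr(mu * math.sqrt(n2 / 2.0) - norm.ppf(1.0 - alpha))
    return float(out) if out.ndim == 0 else out


def single_stage_n2(delta: float, alpha: float, beta: float, integer: bool = False) -> float:
    """Per-arm sample size of a two-arm trial: 2 (z_{1-a} + z_{1-b})^2 / delta^2.

    Continuous by default; ``integer=True`` rounds up.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0 (delta = 0 needs infinite sample size)")
    n2 = 2.0 * (norm.ppf(1.0 - alpha) + norm.ppf(1.0 - beta)) ** 2 / delta**2
    return float(math.ceil(n2)) if integer else n2


@lru_cache(maxsize=None)
def dunnett_c2(i: int, alpha: float) -> float:
    """Critical value controlling the FWER of i arms vs a shared control.

    Solves P(max_{1..i} Z > c) = alpha for equicorrelated (rho = 1/2)
    standard normal Z, by conditioning on the shared control variate:

        P(max Z <= c) = E_W[ Phi(W + sqrt(2) c)^i ],  W ~ N(0,1).
    """
    if i < 1:
        raise ValueError(f"i must be >= 1, got {i}")
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    if i == 1:
        return float(norm.ppf(1.0 - alpha))

    w, wt = _gauss_hermite_std(101)

    def fwer_minus_alpha(c):
        return 1.0 - float(wt @ ndtr(w + math.sqrt(2.0) * c) ** i) - alpha

    lo = norm.ppf(1.0 - alpha)
    hi = norm.ppf(1.0 - alpha / (2.0 * i))  # Bonferroni-ish upper bracket
    return float(optimize.brentq(fwer_minus_alpha, lo, hi + 0.5, xtol=_C2_XTOL))


def multiarm_n2(i: int, delta: float, alpha: float, beta: float, integer: bool = False) -> float:
    """Per-arm size of an i-arm confirmatory trial with marginal power 1-beta.

    The marginal statistic of the prespecified arm is N(delta sqrt(n2/2), 1),
    so the power constraint P(Z_1 > c2(i)) = 1 - beta gives the closed form
    n2 = 2 (c2(i) + z_{1-beta})^2 / delta^2.  Agrees with
    :func:`single_stage_n2` at i = 1 and is nondecreasing in i.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    c2 = dunnett_c2(i, alpha)
    n2 = 2.0 * (c2 + norm.ppf(1.0 - beta)) ** 2 / delta**2
    return float(math.ceil(n2)) if integer else n2


def multiarm_design(K: int, conf: ConfirmatorySpec, integer: bool = False) -> ConfirmatoryDesign:
    """Dunnett-calibrated single-stage designs for every arm count 1..K."""
    n2 = {i: multiarm_n2(i, conf.delta, conf.alpha, conf.beta, integer) for i in range(1, K + 1)}
    c2 = {i: dunnett_c2(i, conf.alpha) for i in range(1, K + 1)}
    return ConfirmatoryDesign(n2_by_arms=n2, c2_by_arms=c2, n2_integer=integer)


@lru_cache(maxsize=8)
def _gauss_hermite_std(n: int):
    """Probabilists' Gauss-Hermite nodes/weights for E[f(W)], W ~ N(0,1)."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / math.sqrt(2.0 * math.pi)


def fwer_attained(c2: float, i: int) -> tuple[float, float]:
    """Attained FWER at critical value c2 with i arms, and a quadrature check.

    Returns (value from 101-node quadrature, value from adaptive quad);
    exposed for diagnostics and the defining-equation tests.
    """
    w, wt = _gauss_hermite_std(101)
    gh = 1.0 - float(wt @ ndtr(w + math.sqrt(2.0) * c2) ** i)
    val, _ = integrate.quad(
        lambda u: norm.pdf(u) * ndtr(u + math.sqrt(2.0) * c2) ** i, -9, 9, limit=200
    )
    return gh, 1.0 - val
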