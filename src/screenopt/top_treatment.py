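"""Top-treatment screening with a single-stage confirmatory trial.

Progression rule: the best-performing screening arm proceeds to a two-arm
confirmatory trial iff its z-statistic exceeds c1.  All operating
characteristics are prior-predictive: treatment effects are integrated
over the exchangeable prior N(m0, v0^2).

The selection probability for a given treatment conditions on that
treatment's screening sample mean x, whose marginal law is
N(m0, v0^2 + 1/n1).  Given x,

* the K-1 exchangeable competitors are each beaten with probability
  Phi_m(x), Phi_m the N(m0, v0^2 + 1/n1) CDF, independently;
* the threshold event Z_i > c1 becomes, after integrating the control
  sample mean N(0, 1/n1) analytically, Phi( sqrt(n1) (x - c1 sqrt(2/n1)) ).

The joint selection-and-success probability additionally weights by the
confirmatory power R(mu); the inner expectation of R over mu | x is a
normal-CDF closed form, so both quantities reduce to one-dimensional
integrals evaluated with adaptive quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import ndtr
from scipy.stats import norm

from .core import phase3_power_function, single_stage_n2
from .types import ConfirmatorySpec, PriorSpec, ProgramResult, ScreeningDesign, TOP_TREATMENT

__all__ = [
    "prob_recommend_one",
    "prob_success_one",
    "ess_top_single",
    "screening_fwer",
    "screening_power",
]

# integration domains truncated at +-8 marginal SDs; absolute tolerance 1e-10
_NSD = 8.0
_EPSABS = 1e-10


def _selection_kernel(x, design: ScreeningDesign, prior: PriorSpec):
    """Density x selection factor: f_m(x) * Phi(ctrl beaten) * Phi_m(x)^(K-1)."""
    K, n1, c1 = design.K, design.n1, design.c1
    s1 = math.sqrt(prior.v0**2 + 1.0 / n1)
    dens = norm.pdf(x, prior.m0, s1)
    ctrl = ndtr(math.sqrt(n1) * (x - c1 * math.sqrt(2.0 / n1)))
    beat = ndtr((x - prior.m0) / s1) ** (K - 1)
    return dens * ctrl * beat


def prob_recommend_one(design: ScreeningDesign, prior: PriorSpec) -> float:
    """Prior-predictive probability that a *given* treatment is recommended.

    The probability that any treatment is recommended (a confirmatory
    trial is conducted) is K times this, by exchangeability.
    """
    s1 = math.sqrt(prior.v0**2 + 1.0 / design.n1)
    lo, hi = prior.m0 - _NSD * s1, prior.m0 + _NSD * s1
    val, err = integrate.quad(
        _selection_kernel, lo, hi, args=(design, prior), limit=200, epsabs=_EPSABS
    )
    return float(val)


def prob_success_one(
    design: ScreeningDesign, prior: PriorSpec, conf: ConfirmatorySpec, n2: float | None = None
) -> float:
    """Prior-predictive probability a given treatment is recommended *and*
    wins its confirmatory trial.

    Weights the selection kernel by E[R(mu) | x]: with mu | x normal
    (posterior mean m_post(x), variance v_post^2) and
    R(mu) = Phi(a mu - b), the inner expectation is
    Phi( (a m_post - b) / sqrt(1 + a^2 v_post^2) ).
    """
    if conf.J != 1:
        raise ValueError("prob_success_one is the single-stage (J=1) path")
    if n2 is None:
        n2 = single_stage_n2(conf.delta, conf.alpha, conf.beta)
    n1, m0, v0 = design.n1, prior.m0, prior.v0
    a = math.sqrt(n2 / 2.0)
    b = norm.ppf(1.0 - conf.alpha)
    if v0 == 0.0:
        # degenerate prior: every effect equals m0, success independent of x
        return phase3_power_function(m0, n2, conf.alpha) * prob_recommend_one(design, prior)
    v_post2 = 1.0 / (1.0 / v0**2 + n1)
    scale = math.sqrt(1.0 + a * a * v_post2)

    def integrand(x):
        m_post = v_post2 * (m0 / v0**2 + n1 * x)
        return _selection_kernel(x, design, prior) * ndtr((a * m_post - b) / scale)

    s1 = math.sqrt(v0**2 + 1.0 / n1)
    val, err = integrate.quad(
        integrand, m0 - _NSD * s1, m0 + _NSD * s1, limit=200, epsabs=_EPSABS
    )
    return float(val)


def screening_fwer(design: ScreeningDesign) -> float:
    """P(any screening z-statistic exceeds c1) when all effects are zero.

    The statistics are equicorrelated (rho = 1/2) standard normal; the
    probability is computed by integrating out the shared control mean.
    """
    K, n1, c1 = design.K, design.n1, design.c1
    sd0 = 1.0 / math.sqrt(n1)
    thresh = c1 * math.sqrt(2.0 / n1)

    def none_cross(u):
        return norm.pdf(u, 0.0, sd0) * ndtr(math.sqrt(n1) * (u + thresh)) ** K

    val, _ = integrate.quad(none_cross, -_NSD * sd0, _NSD * sd0, limit=200, epsabs=_EPSABS)
    return float(1.0 - val)


def screening_power(design: ScreeningDesign, delta: float) -> float:
    """P(the treatment with effect delta is selected), other effects zero."""
    K, n1, c1 = design.K, design.n1, design.c1
    sd = 1.0 / math.sqrt(n1)
    thresh = c1 * math.sqrt(2.0 / n1)

    def integrand(x):
        ctrl = ndtr(math.sqrt(n1) * (x - thresh))
        beat = ndtr(math.sqrt(n1) * x) ** (K - 1)
        return norm.pdf(x, delta, sd) * ctrl * beat

    val, _ = integrate.quad(
        integrand, delta - _NSD * sd, delta + _NSD * sd, limit=200, epsabs=_EPSABS
    )
    return float(val)


def ess_top_single(
    design: ScreeningDesign,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    integer_n2: bool = False,
    operating_characteristics: bool = False,
) -> ProgramResult:
    """Expected sample size until first phase III success (renewal identity).

    Cycles are i.i.d. (fresh treatments each cycle), so

        ESS = [ (K+1) n1 + 2 n2 E(P1) ] / E(P2),

    with E(P1) = K * prob_recommend_one and E(P2) = K * prob_success_one.
    """
    if conf.rule != TOP_TREATMENT:
        raise ValueError("ess_top_single applies to the top-treatment rule")
    if conf.J != 1:
        raise ValueError("use ess_top_groupseq for multi-stage confirmatory trials")
    n2 = single_stage_n2(conf.delta, conf.alpha, conf.beta, integer=integer_n2)
    p1 = design.K * prob_recommend_one(design, prior)
    p2 = design.K * prob_success_one(design, prior, conf, n2=n2)
    if p2 <= 0.0:
        ess = math.inf
    else:
        ess = (design.screening_ss + 2.0 * n2 * p1) / p2
    res = ProgramResult(ess=ess, p_conduct=p1, p_success=p2, diagnostics={"n2": n2})
    if operating_characteristics:
        res.fwer = screening_fwer(design)
        res.power = screening_power(design, conf.delta)
    return res
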