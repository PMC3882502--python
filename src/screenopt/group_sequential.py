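"""Triangular group-sequential confirmatory designs and the top-treatment ESS.

A J-stage confirmatory trial analyses cumulative z-statistics Z_1..Z_J at
equal information increments (per-arm per-stage size g, information
fraction t_j = j/J, corr(Z_j, Z_k) = sqrt(j/k)).  The triangular boundary
family on the z scale is

    u_j = C (1 + t_j) / sqrt(t_j)        (efficacy)
    l_j = -C (1 - 3 t_j) / sqrt(t_j)     (futility; l_J = u_J)

with a single shape constant C.  Calibration (the package's convention,
see docs/methods.md): C is chosen so the probability of ever crossing the
efficacy boundary under mu = 0 equals alpha, and g so that the same
crossing probability at mu = delta equals 1 - beta, in both cases treating
the futility boundary as non-binding (ignored).  Futility stops are applied
when computing expected sample sizes and program operating
characteristics.  ``binding=True`` switches both calibrations to honour
the futility boundary.

The same boundary family generalises to multi-arm multi-stage (MAMS)
confirmatory trials: with i experimental arms sharing one control, C is
calibrated so the family-wise probability of any arm ever crossing the
efficacy boundary under the global null equals alpha (Dunnett-type), and g
so the marginal power of a prespecified arm at delta equals 1 - beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import multivariate_normal, norm

from ._bvn import bvn_cdf
from .core import _gauss_hermite_std, dunnett_c2, multiarm_n2, single_stage_n2
from .top_treatment import screening_fwer, screening_power
from .types import ConfirmatorySpec, PriorSpec, ProgramResult, ScreeningDesign, TOP_TREATMENT

__all__ = [
    "GSBoundaries",
    "StopProbabilities",
    "triangular_boundaries",
    "mams_triangular_design",
    "stopping_probabilities",
    "expected_confirmatory_ss",
    "ess_top_groupseq",
]

_GH_NODES = 128


@dataclass(frozen=True)
class GSBoundaries:
    """Calibrated group-sequential boundaries.

    futility/efficacy are per-stage z-scale bounds (l_J = u_J forces a
    final decision); n_per_stage is the per-arm patients per stage;
    stage_ss[j] = N*(j+1) is the total patients (all arms) used if the
    trial stops at analysis j+1; n_arms counts experimental arms.
    """

    J: int
    futility: np.ndarray
    efficacy: np.ndarray
    n_per_stage: float
    n_arms: int = 1
    constant: float | None = None
    binding: bool = False
    attained: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.J != len(self.efficacy) or self.J != len(self.futility):
            raise ValueError("boundary arrays must have length J")
        if abs(self.futility[-1] - self.efficacy[-1]) > 1e-9:
            raise ValueError("final futility and efficacy bounds must coincide")
        if any(self.futility[j] >= self.efficacy[j] for j in range(self.J - 1)):
            raise ValueError("need l_j < u_j before the final analysis")

    @property
    def stage_ss(self) -> np.ndarray:
        """N*(j): total patients (i experimental arms + control) by stage j."""
        return (self.n_arms + 1) * self.n_per_stage * np.arange(1, self.J + 1)

    @property
    def info_times(self) -> np.ndarray:
        return np.arange(1, self.J + 1) / self.J


@dataclass(frozen=True)
class StopProbabilities:
    """Per-stage efficacy / futility stopping probabilities at one effect."""

    efficacy: np.ndarray
    futility: np.ndarray

    def __post_init__(self):
        tot = self.efficacy.sum() + self.futility.sum()
        if abs(tot - 1.0) > 1e-8:
            raise ValueError(f"stopping probabilities must sum to 1, got {tot}")


def _triangular_shape(C: float, J: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(1, J + 1) / J
    u = C * (1.0 + t) / np.sqrt(t)
    l = -C * (1.0 - 3.0 * t) / np.sqrt(t)
    l[-1] = u[-1]
    return l, u


def _stage_corr(J: int) -> np.ndarray:
    j = np.arange(1, J + 1, dtype=float)
    return np.sqrt(np.minimum.outer(j, j) / np.maximum.outer(j, j))


def _rect_prob(lower, upper, mean, cov) -> float:
    """P(lower < Z <= upper) for Z ~ N(mean, cov); BVN fast paths for dim <= 2."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    mean = np.asarray(mean, float)
    dim = len(mean)
    sd = np.sqrt(np.diag(cov))
    lo = (lower - mean) / sd
    hi = (upper - mean) / sd
    if dim == 1:
        return float(ndtr(hi[0]) - ndtr(lo[0]))
    if dim == 2:
        r = cov[0, 1] / (sd[0] * sd[1])
        return float(
            bvn_cdf(hi[0], hi[1], r)
            - bvn_cdf(lo[0], hi[1], r)
            - bvn_cdf(hi[0], lo[1], r)
            + bvn_cdf(lo[0], lo[1], r)
        )
    corr = cov / np.outer(sd, sd)
    return float(
        multivariate_normal.cdf(hi, mean=np.zeros(dim), cov=corr, lower_limit=lo)
    )


def _stage_probs(l, u, mean, cov) -> tuple[np.ndarray, np.ndarray]:
    """Per-stage (efficacy, futility) stop probabilities for Z ~ N(mean, cov),
    honouring both boundaries in conduct."""
    J = len(u)
    eff = np.zeros(J)
    fut = np.zeros(J)
    big = np.inf
    for j in range(J):
        lo_e = np.concatenate([l[:j], [u[j]]])
        hi_e = np.concatenate([u[:j], [big]])
        eff[j] = _rect_prob(lo_e, hi_e, mean[: j + 1], cov[: j + 1, : j + 1])
        lo_f = np.concatenate([l[:j], [-big]])
        hi_f = np.concatenate([u[:j], [l[j] if j < J - 1 else u[j]]])
        fut[j] = _rect_prob(lo_f, hi_f, mean[: j + 1], cov[: j + 1, : j + 1])
    return np.clip(eff, 0.0, 1.0), np.clip(fut, 0.0, 1.0)


def _crossing_prob(l, u, mean, cov, binding: bool) -> float:
    """P(ever cross the efficacy boundary); futility ignored if non-binding."""
    J = len(u)
    if not binding:
        # 1 - P(Z_j < u_j for all j)
        return 1.0 - _rect_prob(np.full(J, -np.inf), u, mean, cov)
    eff, _ = _stage_probs(l, u, mean, cov)
    return float(eff.sum())


def _drift(mu: float, g: float, J: int) -> np.ndarray:
    return mu * np.sqrt(np.arange(1, J + 1) * g / 2.0)


def triangular_boundaries(
    conf: ConfirmatorySpec, binding: bool = False, integer_n: bool = False
) -> GSBoundaries:
    """Calibrate the two-arm triangular design for a confirmatory spec.

    J = 1 degenerates to the single-stage design u_1 = z_{1-alpha},
    n = single_stage_n2.
    """
    J = conf.J
    alpha, beta, delta = conf.alpha, conf.beta, conf.delta
    if J == 1:
        zca = float(norm.ppf(1.0 - alpha))
        g = single_stage_n2(delta, alpha, beta, integer=integer_n)
        return GSBoundaries(
            J=1,
            futility=np.array([zca]),
            efficacy=np.array([zca]),
            n_per_stage=g,
            constant=zca / 2.0,
            binding=binding,
            attained={"alpha": alpha, "power": 1.0 - beta},
        )
    corr = _stage_corr(J)
    zero = np.zeros(J)

    def alpha_err(C):
        l, u = _triangular_shape(C, J)
        return _crossing_prob(l, u, zero, corr, binding) - alpha

    C = float(optimize.brentq(alpha_err, 0.3, 3.0, xtol=1e-10))
    l, u = _triangular_shape(C, J)

    def power_err(g):
        return _crossing_prob(l, u, _drift(delta, g, J), corr, binding) - (1.0 - beta)

    g = float(optimize.brentq(power_err, 1.0, 1e5, xtol=1e-8))
    if integer_n:
        g = float(math.ceil(g))
    attained = {
        "alpha": _crossing_prob(l, u, zero, corr, binding),
        "power": _crossing_prob(l, u, _drift(delta, g, J), corr, binding),
        "alpha_with_futility": float(_stage_probs(l, u, zero, corr)[0].sum()),
        "power_with_futility": float(_stage_probs(l, u, _drift(delta, g, J), corr)[0].sum()),
    }
    return GSBoundaries(
        J=J, futility=l, efficacy=u, n_per_stage=g, constant=C, binding=binding,
        attained=attained,
    )


def stopping_probabilities(b: GSBoundaries, mu: float) -> StopProbabilities:
    """Per-stage efficacy/futility stopping probabilities at effect mu
    (two-arm trial; futility boundary applied)."""
    corr = _stage_corr(b.J)
    eff, fut = _stage_probs(b.futility, b.efficacy, _drift(mu, b.n_per_stage, b.J), corr)
    return StopProbabilities(efficacy=eff, futility=fut)


def expected_confirmatory_ss(b: GSBoundaries, mu: float, success_only: bool = False) -> float:
    """E[N] (total patients, both arms) of the confirmatory trial at effect mu;
    ``success_only`` restricts to trajectories ending in efficacy
    (an unnormalised expectation, E[N; success])."""
    sp = stopping_probabilities(b, mu)
    w = sp.efficacy if success_only else sp.efficacy + sp.futility
    return float(w @ b.stage_ss)


def _mams_fwer(l, u, g_unused, i: int, binding: bool) -> float:
    """FWER of an i-arm MAMS trial under the global null (J = 2 only).

    Conditionally on the control's standardized stage increments
    (b1, b2), arms are independent with (Z_1, Z_2) normal: means
    (-b1/sqrt(2), -(b1+b2)/2), variances 1/2, correlation 1/sqrt(2).
    """
    x, wt = _gauss_hermite_std(48)
    B1, B2 = np.meshgrid(x, x, indexing="ij")
    m1 = -B1 / math.sqrt(2.0)
    m2 = -(B1 + B2) / 2.0
    s = math.sqrt(0.5)
    r = 1.0 / math.sqrt(2.0)
    if not binding:
        no_cross = bvn_cdf((u[0] - m1) / s, (u[1] - m2) / s, r)
    else:
        h1u = (u[0] - m1) / s
        h1l = (l[0] - m1) / s
        h2 = (u[1] - m2) / s
        # stay below u1; if below l1 the arm is dropped (cannot cross later)
        no_cross = ndtr(h1l) + (bvn_cdf(h1u, h2, r) - bvn_cdf(h1l, h2, r))
    inner = no_cross**i
    return 1.0 - float(np.einsum("i,j,ij->", wt, wt, inner))


def mams_triangular_design(
    i: int, conf: ConfirmatorySpec, binding: bool = False
) -> GSBoundaries:
    """Triangular MAMS design for i experimental arms sharing one control.

    J = 1 reduces exactly to the Dunnett design (c2(i), n2(i)).  For J = 2
    the shape constant is calibrated so the family-wise efficacy-crossing
    probability under the global null is alpha, and the per-stage size so
    the marginal power of a prespecified arm at delta is 1 - beta.
    """
    if i == 1:
        return triangular_boundaries(conf, binding=binding)
    J, alpha, beta, delta = conf.J, conf.alpha, conf.beta, conf.delta
    if J == 1:
        c2 = dunnett_c2(i, alpha)
        g = multiarm_n2(i, delta, alpha, beta)
        return GSBoundaries(
            J=1, futility=np.array([c2]), efficacy=np.array([c2]), n_per_stage=g,
            n_arms=i, constant=c2 / 2.0, binding=binding,
            attained={"alpha": alpha, "power": 1.0 - beta},
        )
    if J != 2:
        raise NotImplementedError("MAMS calibration implemented for J <= 2")

    def fwer_err(C):
        l, u = _triangular_shape(C, J)
        return _mams_fwer(l, u, None, i, binding) - alpha

    C = float(optimize.brentq(fwer_err, 0.3, 3.0, xtol=1e-10))
    l, u = _triangular_shape(C, J)
    corr = _stage_corr(J)

    def power_err(g):
        # marginal single-arm crossing probability; control integrates out
        return _crossing_prob(l, u, _drift(delta, g, J), corr, binding) - (1.0 - beta)

    g = float(optimize.brentq(power_err, 1.0, 1e5, xtol=1e-8))
    return GSBoundaries(
        J=J, futility=l, efficacy=u, n_per_stage=g, n_arms=i, constant=C,
        binding=binding,
        attained={"fwer": _mams_fwer(l, u, None, i, binding) ,
                  "marginal_power": _crossing_prob(l, u, _drift(delta, g, J), corr, binding)},
    )


def ess_top_groupseq(
    design: ScreeningDesign,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    boundaries: GSBoundaries | None = None,
    binding: bool = False,
    operating_characteristics: bool = False,
) -> ProgramResult:
    """ESS for top-treatment screening with a group-sequential confirmatory
    trial.

    Writing psi for the selected treatment (0 = none), chi for the
    confirmatory outcome and N for the realized confirmatory sample size,

        ESS = [ (K+1) n1 + E(N; psi!=0, chi=0) + E(N; psi!=0, chi=1) ]
              / P(psi!=0, chi=1).

    Conditioning on the selected treatment's screening sample mean x
    reduces each joint expectation to a one-dimensional integral: given x,
    mu is normal (posterior mean/variance), and mixing the stage statistics
    over mu | x keeps them jointly normal with covariance inflated by the
    posterior variance, so stage-stopping probabilities stay
    multivariate-normal rectangles.
    """
    if conf.rule != TOP_TREATMENT:
        raise ValueError("ess_top_groupseq applies to the top-treatment rule")
    b = boundaries if boundaries is not None else triangular_boundaries(conf, binding=binding)
    K, n1, c1 = design.K, design.n1, design.c1
    m0, v0 = prior.m0, prior.v0
    J, g = b.J, b.n_per_stage
    d = np.sqrt(np.arange(1, J + 1) * g / 2.0)
    corr = _stage_corr(J)
    nstar = b.stage_ss

    s1 = math.sqrt(v0**2 + 1.0 / n1)
    v_post2 = 0.0 if v0 == 0.0 else 1.0 / (1.0 / v0**2 + n1)
    cov = corr + v_post2 * np.outer(d, d)

    x, wt = _gauss_hermite_std(_GH_NODES)
    xs = m0 + s1 * x  # nodes of the marginal N(m0, s1^2) of the screening mean
    ctrl = ndtr(np.sqrt(n1) * (xs - c1 * math.sqrt(2.0 / n1)))
    beat = ndtr((xs - m0) / s1) ** (K - 1)
    sel = wt * ctrl * beat

    p_succ = 0.0
    en_eff = 0.0
    en_fut = 0.0
    for w_i, x_i in zip(sel, xs):
        if w_i < 1e-16:
            continue
        m_post = m0 if v0 == 0.0 else v_post2 * (m0 / v0**2 + n1 * x_i)
        eff, fut = _stage_probs(b.futility, b.efficacy, m_post * d, cov)
        p_succ += w_i * eff.sum()
        en_eff += w_i * float(eff @ nstar)
        en_fut += w_i * float(fut @ nstar)
    p_succ *= K
    en_eff *= K
    en_fut *= K
    p_conduct = K * float(sel.sum())

    ess = (design.screening_ss + en_eff + en_fut) / p_succ if p_succ > 0 else math.inf
    res = ProgramResult(
        ess=ess, p_conduct=p_conduct, p_success=p_succ,
        diagnostics={
            "boundaries": b,
            "e_n_success": en_eff,
            "e_n_fail": en_fut,
        },
    )
    if operating_characteristics:
        res.fwer = screening_fwer(design)
        res.power = screening_power(design, conf.delta)
    return res
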