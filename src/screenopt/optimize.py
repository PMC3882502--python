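"""Screening-design optimization: Nelder-Mead over (n1, c1), integer
refinement of n1, and the scan over the number of screening arms K.

The objective is the family's ESS at fixed K.  n1 is optimized on a
log-transformed scale (n1 = 1 + exp(s)) so the n1 >= 1 bound never needs a
penalty; c1 is unconstrained.  After the continuous optimum, c1 is
re-optimized one-dimensionally at the floor and ceiling integers of n1 and
the better integer design is returned.  The design minimizing ESS over all
scanned K is the optimal screening design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .all_interesting import ess_all_interesting
from .group_sequential import ess_top_groupseq, triangular_boundaries
from .mams_sim import DatasetBank, build_bank, ess_mams
from .top_treatment import ess_top_single, screening_fwer, screening_power
from .types import (
    ALL_INTERESTING,
    ConfirmatorySpec,
    PriorSpec,
    ScreeningDesign,
    TOP_TREATMENT,
)

__all__ = ["DesignRow", "OptimizationResult", "ess_function", "optimize_design",
           "scan_K", "sensitivity_at"]


@dataclass(frozen=True)
class DesignRow:
    K: int
    n1: int
    c1: float
    ess: float
    fwer: float | None = None
    power: float | None = None
    quantile95: float | None = None


@dataclass
class OptimizationResult:
    per_K: list
    best: DesignRow
    trace: dict = field(default_factory=dict)


def ess_function(prior: PriorSpec, conf: ConfirmatorySpec, bank: DatasetBank | None = None,
                 binding: bool = False):
    """Return f(K, n1, c1) -> ESS for the (rule, J) family of ``conf``.

    Analytic paths for top-treatment (any J) and single-stage
    all-interesting; the simulation bank backs all-interesting with J > 1.
    """
    if conf.rule == TOP_TREATMENT:
        if conf.J == 1:
            def f(K, n1, c1):
                return ess_top_single(ScreeningDesign(K, n1, c1), prior, conf).ess
        else:
            b = triangular_boundaries(conf, binding=binding)

            def f(K, n1, c1):
                return ess_top_groupseq(
                    ScreeningDesign(K, n1, c1), prior, conf, boundaries=b
                ).ess
    elif conf.J == 1:
        def f(K, n1, c1):
            return ess_all_interesting(ScreeningDesign(K, n1, c1), prior, conf).ess
    else:
        if bank is None:
            raise ValueError("all-interesting with J > 1 needs a DatasetBank")

        def f(K, n1, c1):
            return ess_mams(ScreeningDesign(K, n1, c1), prior, conf, bank,
                            binding=binding).ess
    return f


def _nm(f, start, steps, xatol=1e-4, fatol=1e-3, maxiter=600):
    simplex = np.array([start,
                        [start[0] + steps[0], start[1]],
                        [start[0], start[1] + steps[1]]])
    return sopt.minimize(
        f, start, method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": xatol, "fatol": fatol,
                 "maxiter": maxiter, "maxfev": maxiter},
    )


def optimize_design(
    K: int,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    bank: DatasetBank | None = None,
    binding: bool = False,
    start: tuple = (20.0, 0.5),
    n_restarts: int = 3,
) -> tuple[int, float, float]:
    """Minimize ESS over (n1, c1) at fixed K; returns (n1_opt, c1_opt, ess).

    Continuous Nelder-Mead on (s, c1) with n1 = 1 + exp(s), restarted from
    deterministically perturbed starts, then 1-D re-optimization of c1 at
    the floor and ceiling integers of the continuous optimum.
    """
    fun = ess_function(prior, conf, bank=bank, binding=binding)

    def obj(p):
        n1 = 1.0 + math.exp(p[0])
        val = fun(K, n1, p[1])
        return val if math.isfinite(val) else 1e12

    s0 = math.log(max(start[0] - 1.0, 0.5))
    starts = [(s0, start[1])]
    for r in range(1, n_restarts):
        starts.append((s0 + 0.35 * r * (-1) ** r, start[1] - 0.4 * r * (-1) ** r))
    best = None
    for st in starts:
        res = _nm(obj, list(st), steps=[0.5, 0.5])
        if best is None or res.fun < best.fun:
            best = res
    n1_cont = 1.0 + math.exp(best.x[0])
    c1_cont = best.x[1]

    cands = sorted({max(1, math.floor(n1_cont)), max(1, math.ceil(n1_cont))})
    rows = []
    for n1_int in cands:
        r = sopt.minimize_scalar(
            lambda c: fun(K, float(n1_int), c),
            bounds=(c1_cont - 1.0, c1_cont + 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        rows.append((n1_int, float(r.x), float(r.fun)))
    n1_opt, c1_opt, ess = min(rows, key=lambda t: t[2])
    return n1_opt, c1_opt, ess


def scan_K(
    K_range,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    bank: DatasetBank | None = None,
    binding: bool = False,
    operating_characteristics: bool = True,
) -> OptimizationResult:
    """Optimize per K and mark the argmin; one shared bank (common random
    numbers) backs every K for simulation objectives."""
    rows = []
    trace = {}
    for K in K_range:
        n1, c1, ess = optimize_design(K, prior, conf, bank=bank, binding=binding)
        d = ScreeningDesign(K, float(n1), c1)
        row = DesignRow(
            K=K, n1=n1, c1=c1, ess=ess,
            fwer=screening_fwer(d) if operating_characteristics else None,
            power=screening_power(d, conf.delta) if operating_characteristics else None,
        )
        rows.append(row)
        trace[K] = (n1, c1, ess)
    best = min(rows, key=lambda r: r.ess)
    return OptimizationResult(per_K=rows, best=best, trace=trace)


def sensitivity_at(
    K: int,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    n1: float | None = None,
    c1: float | None = None,
    bank: DatasetBank | None = None,
    binding: bool = False,
) -> float:
    """Percentage ESS increase from pinning n1 and/or c1 away from the optimum.

    The free coordinate(s) are re-optimized under the pin; the reference is
    the unpinned optimum at the same K.
    """
    fun = ess_function(prior, conf, bank=bank, binding=binding)
    n1_opt, c1_opt, ess_opt = optimize_design(K, prior, conf, bank=bank, binding=binding)
    if n1 is None and c1 is None:
        return 0.0
    if n1 is not None and c1 is not None:
        ess_pin = fun(K, float(n1), float(c1))
    elif c1 is not None:
        r = sopt.minimize_scalar(
            lambda s: fun(K, 1.0 + math.exp(s), float(c1)),
            bounds=(0.0, 6.0), method="bounded", options={"xatol": 1e-6},
        )
        ess_pin = float(r.fun)
    else:
        r = sopt.minimize_scalar(
            lambda c: fun(K, float(n1), c),
            bounds=(c1_opt - 2.0, c1_opt + 2.0), method="bounded",
            options={"xatol": 1e-6},
        )
        ess_pin = float(r.fun)
    return 100.0 * (ess_pin / ess_opt - 1.0)
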