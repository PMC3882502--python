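"""Simulation engine with a reusable dataset bank.

For design families without an analytic ESS path (all-interesting
screening feeding a multi-arm multi-stage confirmatory trial), program
operating characteristics are estimated by simulation.  A
:class:`DatasetBank` stores design-independent standard-normal increments
and prior effect draws once; any candidate (n1, c1) is evaluated on the
same draws by rescaling (exact for the normal model), giving common random
numbers across candidate designs so the simulated ESS surface is smooth
enough for Nelder-Mead.

The bank stores, per replicate: treatment effects mu ~ N(m0, v0^2); one
standard-normal deviate per screening arm (screening sample mean =
mu + e / sqrt(n1)); and per-stage standard-normal increments for every
potential confirmatory arm (cumulative sample mean after j stages of
per-arm stage size g = mu + (e_1 + .. + e_j) / (j sqrt(g)) / ... scaled
exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .group_sequential import GSBoundaries, mams_triangular_design, triangular_boundaries
from .types import (
    ALL_INTERESTING,
    ConfirmatorySpec,
    PriorSpec,
    ProgramResult,
    ScreeningDesign,
    TOP_TREATMENT,
)

__all__ = [
    "DatasetBank",
    "build_bank",
    "estimate_phase3_quantities",
    "ess_mams",
    "simulate_ss_quantile",
]


@dataclass(frozen=True)
class DatasetBank:
    """Reusable matrix of simulated effects and standard-normal noise.

    Identical (seed, n_reps, K_max, J_max, prior) give bit-identical banks.
    """

    effects: np.ndarray       # (n_reps, K_max)
    screen_treat: np.ndarray  # (n_reps, K_max)
    screen_ctrl: np.ndarray   # (n_reps,)
    conf_treat: np.ndarray    # (n_reps, K_max, J_max) per-stage increments
    conf_ctrl: np.ndarray     # (n_reps, J_max)
    prior: PriorSpec
    seed: int
    n_reps: int

    @property
    def K_max(self) -> int:
        return self.effects.shape[1]

    @property
    def J_max(self) -> int:
        return self.conf_ctrl.shape[1]


def build_bank(
    K_max: int, prior: PriorSpec, n_reps: int, seed: int, J_max: int = 2
) -> DatasetBank:
    """Draw a dataset bank; deterministic in ``seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    effects = rng.normal(prior.m0, prior.v0, size=(n_reps, K_max))
    screen_treat = rng.standard_normal((n_reps, K_max))
    screen_ctrl = rng.standard_normal(n_reps)
    conf_treat = rng.standard_normal((n_reps, K_max, J_max))
    conf_ctrl = rng.standard_normal((n_reps, J_max))
    return DatasetBank(
        effects=effects, screen_treat=screen_treat, screen_ctrl=screen_ctrl,
        conf_treat=conf_treat, conf_ctrl=conf_ctrl, prior=prior, seed=seed,
        n_reps=n_reps,
    )


def _cumulative_z(mu, treat_inc, ctrl_inc, g: float):
    """Stage-wise z-statistics of arms vs control from per-stage increments.

    mu: (m, i) effects; treat_inc: (m, i, J); ctrl_inc: (m, J); returns
    (m, i, J).  Stage s contributes g patients whose sum is
    g mu + sqrt(g) inc_s, so the cumulative per-arm mean after j stages is
    mu + cumsum(inc)_j / (j sqrt(g)), with variance 1/(j g) as required.
    """
    J = ctrl_inc.shape[-1]
    j = np.arange(1, J + 1, dtype=float)
    tmean = mu[..., None] + np.cumsum(treat_inc, axis=-1) / (j * np.sqrt(g))
    cmean = np.cumsum(ctrl_inc, axis=-1) / (j * np.sqrt(g))
    return (tmean - cmean[:, None, :]) * np.sqrt(j * g / 2.0)


def _run_confirmatory(mu_sel, treat_inc, ctrl_inc, b: GSBoundaries):
    """Simulate an i-arm confirmatory trial with boundaries b.

    mu_sel: (m, i) selected effects; treat_inc (m, i, >=J); ctrl_inc (m, >=J).
    Returns (success (m,), ss (m,), winner (m,) column index or -1).
    Arms are dropped at futility; the trial stops at the first analysis any
    arm crosses efficacy (winner = largest crossing statistic) or when no
    arm remains; the control accrues with the surviving arms.
    """
    m, i = mu_sel.shape
    J, g = b.J, b.n_per_stage
    z = _cumulative_z(mu_sel, treat_inc[:, :, :J], ctrl_inc[:, :J], g)
    active = np.ones((m, i), dtype=bool)
    done = np.zeros(m, dtype=bool)
    success = np.zeros(m, dtype=bool)
    winner = np.full(m, -1)
    ss = np.zeros(m)
    for j in range(J):
        ss = np.where(done, ss, ss + (active.sum(axis=1) + 1) * g)
        zj = np.where(active, z[:, :, j], -np.inf)
        crossed = zj >= b.efficacy[j]
        any_cross = crossed.any(axis=1) & ~done
        if any_cross.any():
            zc = np.where(crossed[any_cross], zj[any_cross], -np.inf)
            winner[any_cross] = zc.argmax(axis=1)
            success |= any_cross
            done |= any_cross
        active &= zj > b.futility[j]
        dead = ~active.any(axis=1) & ~done
        done |= dead
    return success, ss, winner


def estimate_phase3_quantities(
    design: ScreeningDesign,
    conf: ConfirmatorySpec,
    bank: DatasetBank,
    binding: bool = False,
) -> dict:
    """Per-replicate screening + confirmatory simulation on the bank.

    Returns p_conduct, p_success_given_conduct, e_ss_fail, e_ss_success
    (confirmatory patients when the trial fails / succeeds) with standard
    errors.
    """
    K, n1, c1 = design.K, design.n1, design.c1
    if bank.K_max < K:
        raise ValueError(f"bank holds {bank.K_max} arms, design needs {K}")
    if bank.J_max < conf.J:
        raise ValueError(f"bank holds {bank.J_max} stages, spec needs {conf.J}")
    mu = bank.effects[:, :K]
    xbar = mu + bank.screen_treat[:, :K] / math.sqrt(n1)
    x0 = bank.screen_ctrl / math.sqrt(n1)
    z = (xbar - x0[:, None]) * math.sqrt(n1 / 2.0)

    if conf.rule == TOP_TREATMENT:
        passed = np.zeros_like(z, dtype=bool)
        top = z.argmax(axis=1)
        rows = np.arange(bank.n_reps)
        passed[rows, top] = z[rows, top] > c1
    else:
        passed = z > c1
    counts = passed.sum(axis=1)

    R = bank.n_reps
    conducted = counts > 0
    succ = np.zeros(R, dtype=bool)
    conf_ss = np.zeros(R)
    for i in np.unique(counts[conducted]):
        b = mams_triangular_design(int(i), conf, binding=binding)
        sel = counts == i
        idx = np.nonzero(sel)[0]
        arm_idx = np.nonzero(passed[sel])[1].reshape(len(idx), int(i))
        mu_sel = mu[idx[:, None], arm_idx]
        treat_inc = bank.conf_treat[idx[:, None], arm_idx, :]
        ctrl_inc = bank.conf_ctrl[idx]
        s, ss, _ = _run_confirmatory(mu_sel, treat_inc, ctrl_inc, b)
        succ[idx] = s
        conf_ss[idx] = ss

    p_conduct = conducted.mean()
    if not conducted.any():
        raise RuntimeError("no replicate conducted a confirmatory trial; "
                           "estimates are degenerate")
    p_sgc = succ[conducted].mean()
    fail = conducted & ~succ
    e_fail = conf_ss[fail].mean() if fail.any() else 0.0
    e_succ = conf_ss[succ].mean() if succ.any() else 0.0
    return {
        "p_conduct": float(p_conduct),
        "p_success_given_conduct": float(p_sgc),
        "e_ss_fail": float(e_fail),
        "e_ss_success": float(e_succ),
        "se_p_conduct": float(math.sqrt(p_conduct * (1 - p_conduct) / R)),
        "se_p_success_given_conduct": float(
            math.sqrt(max(p_sgc * (1 - p_sgc), 0.0) / max(conducted.sum(), 1))
        ),
        "se_e_ss_fail": float(conf_ss[fail].std() / math.sqrt(max(fail.sum(), 1))),
        "se_e_ss_success": float(conf_ss[succ].std() / math.sqrt(max(succ.sum(), 1))),
        "_per_rep": {"succ": succ, "conf_ss": conf_ss},
    }


def ess_mams(
    design: ScreeningDesign,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    bank: DatasetBank,
    binding: bool = False,
) -> ProgramResult:
    """Simulation-based ESS via the renewal identity.

    ESS = E[patients per cycle] / P(cycle success), with both moments
    estimated from the bank; a Monte-Carlo standard error is attached
    (delta method on the ratio).
    """
    if bank.prior != prior:
        raise ValueError("bank was built under a different prior")
    est = estimate_phase3_quantities(design, conf, bank, binding=binding)
    succ = est["_per_rep"]["succ"]
    cyc_ss = design.screening_ss + est["_per_rep"]["conf_ss"]
    R = bank.n_reps
    p = succ.mean()
    if p <= 0:
        return ProgramResult(ess=math.inf, p_conduct=est["p_conduct"], p_success=0.0)
    e = cyc_ss.mean()
    ess = e / p
    # var of ratio of means over the same replicates
    cov = np.cov(cyc_ss, succ.astype(float))
    var = (cov[0, 0] - 2 * ess * cov[0, 1] + ess**2 * cov[1, 1]) / (R * p**2)
    return ProgramResult(
        ess=float(ess),
        p_conduct=est["p_conduct"],
        p_success=float(p),
        diagnostics={
            "ess_se": float(math.sqrt(max(var, 0.0))),
            **{k: v for k, v in est.items() if not k.startswith("_")},
        },
    )


def simulate_ss_quantile(
    design: ScreeningDesign,
    prior: PriorSpec,
    conf: ConfirmatorySpec,
    q: float,
    n_reps: int,
    seed: int,
    binding: bool = False,
    n_boot: int = 200,
    max_cycles: int = 100_000,
) -> dict:
    """Empirical q-quantile of total patients until first phase III success.

    Simulates ``n_reps`` full programs (independent cycles until the first
    confirmatory success) and returns the quantile with a bootstrap SE and
    the mean (which estimates the ESS).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    rng = np.random.default_rng(seed)
    K, n1, c1 = design.K, design.n1, design.c1
    designs = {}

    def conf_design(i):
        if i not in designs:
            designs[i] = mams_triangular_design(i, conf, binding=binding)
        return designs[i]

    totals = np.zeros(n_reps)
    remaining = np.arange(n_reps)
    cycles = 0
    while remaining.size and cycles < max_cycles:
        cycles += 1
        m = remaining.size
        mu = rng.normal(prior.m0, prior.v0, size=(m, K))
        xbar = mu + rng.standard_normal((m, K)) / math.sqrt(n1)
        x0 = rng.standard_normal(m) / math.sqrt(n1)
        z = (xbar - x0[:, None]) * math.sqrt(n1 / 2.0)
        totals[remaining] += (K + 1) * n1
        if conf.rule == TOP_TREATMENT:
            passed = np.zeros_like(z, dtype=bool)
            top = z.argmax(axis=1)
            passed[np.arange(m), top] = z[np.arange(m), top] > c1
        else:
            passed = z > c1
        counts = passed.sum(axis=1)
        succ = np.zeros(m, dtype=bool)
        for i in np.unique(counts[counts > 0]):
            b = conf_design(int(i))
            sel = np.nonzero(counts == i)[0]
            arm_idx = np.nonzero(passed[counts == i])[1].reshape(len(sel), int(i))
            mu_sel = mu[sel[:, None], arm_idx]
            treat_inc = rng.standard_normal((len(sel), int(i), b.J))
            ctrl_inc = rng.standard_normal((len(sel), b.J))
            s, ss, _ = _run_confirmatory(mu_sel, treat_inc, ctrl_inc, b)
            totals[remaining[sel]] += ss
            succ[sel] = s
        remaining = remaining[~succ]
    if remaining.size:
        raise RuntimeError(f"{remaining.size} programs unfinished after {max_cycles} cycles")

    quant = float(np.quantile(totals, q))
    boot = np.empty(n_boot)
    for b_ in range(n_boot):
        boot[b_] = np.quantile(totals[rng.integers(0, n_reps, n_reps)], q)
    return {
        "quantile": quant,
        "q": q,
        "se": float(boot.std()),
        "mean": float(totals.mean()),
        "mean_se": float(totals.std() / math.sqrt(n_reps)),
        "n_reps": n_reps,
        "seed": seed,
    }
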