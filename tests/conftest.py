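"""Shared fixtures and brute-force Monte-Carlo oracles.

The oracles simulate the trial model directly from its definition
(patient-level sample means, shared controls, prior draws) and are kept
independent of the package's quadrature code paths: the only package
symbol they use is the closed-form confirmatory power function, which is
itself pinned against frozen values in test_core.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from screenopt import (
    ConfirmatorySpec,
    PriorSpec,
    ScreeningDesign,
    dunnett_c2,
    multiarm_n2,
    phase3_power_function,
)


@pytest.fixture(scope="session")
def prior_ref():
    """Reference prior used in the main design tables: N(0, 0.1^2)."""
    return PriorSpec(m0=0.0, v0=0.1)


@pytest.fixture(scope="session")
def conf_top_single():
    return ConfirmatorySpec(delta=0.25, alpha=0.025, beta=0.1, J=1, rule="top-treatment")


@pytest.fixture(scope="session")
def conf_all_single():
    return ConfirmatorySpec(delta=0.25, alpha=0.025, beta=0.1, J=1, rule="all-interesting")


@pytest.fixture(scope="session")
def conf_top_gs():
    return ConfirmatorySpec(delta=0.25, alpha=0.025, beta=0.1, J=2, rule="top-treatment")


def mc_top_screening(
    K, n1, c1, m0, v0, n_reps, seed, conf: ConfirmatorySpec | None = None,
    chunk=1_000_000,
):
    """Simulate the screening trial under the prior.

    Returns estimates (with SEs) of: p_rec (a specific treatment is
    selected), and, when ``conf`` is given, p_succ (that treatment is
    selected and wins a single-stage confirmatory trial, success drawn as
    a Bernoulli with the closed-form power at the selected effect).
    """
    rng = np.random.default_rng(seed)
    n2 = None
    if conf is not None:
        n2 = 2 * (_z(1 - conf.alpha) + _z(1 - conf.beta)) ** 2 / conf.delta**2
    rec = succ = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        done += m
        mu = rng.normal(m0, v0, size=(m, K))
        xbar = mu + rng.standard_normal((m, K)) / math.sqrt(n1)
        x0 = rng.standard_normal(m) / math.sqrt(n1)
        z = (xbar - x0[:, None]) * math.sqrt(n1 / 2.0)
        top = z.argmax(axis=1)
        sel = z[np.arange(m), top] > c1
        sel0 = sel & (top == 0)  # specific-treatment selection
        rec += int(sel0.sum())
        if conf is not None:
            mu_sel = mu[np.arange(m), top]
            win = sel0 & (rng.random(m) < phase3_power_function(mu_sel, n2, conf.alpha))
            succ += int(win.sum())
    out = {"p_rec": rec / n_reps, "se_rec": _binom_se(rec, n_reps)}
    if conf is not None:
        out["p_succ"] = succ / n_reps
        out["se_succ"] = _binom_se(succ, n_reps)
    return out


def mc_screening_fixed(K, n1, c1, mu_vec, n_reps, seed, chunk=1_000_000):
    """P(any arm selected) and P(arm 1 selected) at fixed effects mu_vec."""
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu_vec, dtype=float)
    any_sel = first_sel = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        done += m
        xbar = mu + rng.standard_normal((m, K)) / math.sqrt(n1)
        x0 = rng.standard_normal(m) / math.sqrt(n1)
        z = (xbar - x0[:, None]) * math.sqrt(n1 / 2.0)
        top = z.argmax(axis=1)
        sel = z[np.arange(m), top] > c1
        any_sel += int(sel.sum())
        first_sel += int((sel & (top == 0)).sum())
    return {
        "p_any": any_sel / n_reps, "se_any": _binom_se(any_sel, n_reps),
        "p_first": first_sel / n_reps, "se_first": _binom_se(first_sel, n_reps),
    }


def mc_all_interesting(K, n1, c1, m0, v0, conf: ConfirmatorySpec, n_reps, seed,
                       chunk=500_000):
    """Full-program cycle simulation for the all-interesting rule (J = 1).

    Returns the pass-count distribution and the cycle no-success
    probability, simulating the shared confirmatory control explicitly.
    """
    rng = np.random.default_rng(seed)
    n2 = {i: multiarm_n2(i, conf.delta, conf.alpha, conf.beta) for i in range(1, K + 1)}
    c2 = {i: dunnett_c2(i, conf.alpha) for i in range(1, K + 1)}
    counts_tot = np.zeros(K + 1, dtype=np.int64)
    no_succ = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        done += m
        mu = rng.normal(m0, v0, size=(m, K))
        xbar = mu + rng.standard_normal((m, K)) / math.sqrt(n1)
        x0 = rng.standard_normal(m) / math.sqrt(n1)
        z = (xbar - x0[:, None]) * math.sqrt(n1 / 2.0)
        passed = z > c1
        counts = passed.sum(axis=1)
        counts_tot += np.bincount(counts, minlength=K + 1)
        success = np.zeros(m, dtype=bool)
        for i in range(1, K + 1):
            g = n2[i]
            idx = np.nonzero(counts == i)[0]
            if idx.size == 0:
                continue
            arm = np.nonzero(passed[counts == i])[1].reshape(idx.size, i)
            mu_s = mu[idx[:, None], arm]
            ybar = mu_s + rng.standard_normal((idx.size, i)) / math.sqrt(g)
            y0 = rng.standard_normal(idx.size) / math.sqrt(g)
            zc = (ybar - y0[:, None]) * math.sqrt(g / 2.0)
            success[idx] = (zc > c2[i]).any(axis=1)
        no_succ += int(m - success.sum())
    return {
        "p_by_count": counts_tot / n_reps,
        "se_count": np.sqrt(counts_tot * (1 - counts_tot / n_reps)) / n_reps,
        "p_no_success": no_succ / n_reps,
        "se_no_success": _binom_se(no_succ, n_reps),
    }


def _z(p):
    from scipy.stats import norm

    return float(norm.ppf(p))


def _binom_se(k, n):
    p = k / n
    return math.sqrt(max(p * (1 - p), 1e-12) / n)
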