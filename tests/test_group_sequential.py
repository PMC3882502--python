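"""Triangular group-sequential designs and the group-sequential ESS."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from screenopt import (
    ConfirmatorySpec,
    PriorSpec,
    ScreeningDesign,
    ess_top_groupseq,
    ess_top_single,
    expected_confirmatory_ss,
    mams_triangular_design,
    single_stage_n2,
    stopping_probabilities,
    triangular_boundaries,
)


def _simulate_two_stage(b, mu, n, seed):
    """Brute-force simulation of the two-stage two-arm trial."""
    rng = np.random.default_rng(seed)
    g = b.n_per_stage
    e = rng.standard_normal((n, 2))
    f = rng.standard_normal((n, 2))
    z1 = mu * math.sqrt(g / 2) + (e[:, 0] - f[:, 0]) / math.sqrt(2)
    z2 = mu * math.sqrt(g) + (e.sum(1) - f.sum(1)) / 2
    s1e = z1 >= b.efficacy[0]
    s1f = z1 <= b.futility[0]
    cont = ~s1e & ~s1f
    return {
        "eff": np.array([s1e.mean(), (cont & (z2 >= b.efficacy[1])).mean()]),
        "fut": np.array([s1f.mean(), (cont & (z2 < b.efficacy[1])).mean()]),
    }


class TestTriangularBoundaries:
    def test_single_stage_degenerates(self, conf_top_single):
        b = triangular_boundaries(conf_top_single)
        assert b.J == 1
        assert b.efficacy[0] == pytest.approx(norm.ppf(0.975), abs=1e-9)
        assert b.n_per_stage == pytest.approx(single_stage_n2(0.25, 0.025, 0.1), rel=1e-12)

    def test_two_stage_calibration_against_independent_oracle(self, conf_top_gs):
        # attained type-I error and power on the efficacy boundary, checked
        # with scipy's bivariate-normal CDF (a code path the calibration
        # does not use)
        b = triangular_boundaries(conf_top_gs)
        rho = math.sqrt(0.5)
        cov = [[1.0, rho], [rho, 1.0]]

        def crossing(mu):
            d1 = mu * math.sqrt(b.n_per_stage / 2)
            d2 = mu * math.sqrt(b.n_per_stage)
            stay = multivariate_normal.cdf(
                [b.efficacy[0] - d1, b.efficacy[1] - d2], mean=[0, 0], cov=cov
            )
            return 1.0 - stay

        assert crossing(0.0) == pytest.approx(0.025, abs=1e-6)
        assert crossing(0.25) == pytest.approx(0.9, abs=1e-6)

    def test_boundary_shape(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs)
        assert b.futility[0] < b.efficacy[0]
        assert b.futility[1] == pytest.approx(b.efficacy[1], abs=1e-12)
        # z-scale triangular shape: u_j = C (1+t_j)/sqrt(t_j)
        t = np.array([0.5, 1.0])
        expect = b.constant * (1 + t) / np.sqrt(t)
        np.testing.assert_allclose(b.efficacy, expect, rtol=1e-10)

    def test_binding_variant_attains_rates_with_futility(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs, binding=True)
        assert b.attained["alpha_with_futility"] == pytest.approx(0.025, abs=1e-8)
        assert b.attained["power_with_futility"] == pytest.approx(0.9, abs=1e-8)


class TestStoppingProbabilities:
    def test_certain_termination(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs)
        for mu in (-0.2, 0.0, 0.1, 0.3):
            sp = stopping_probabilities(b, mu)
            assert sp.efficacy.sum() + sp.futility.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_two_stage_simulation(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs)
        n = 2_000_000
        for mu, seed in [(0.0, 21), (0.1, 22), (0.25, 23)]:
            sim = _simulate_two_stage(b, mu, n, seed)
            sp = stopping_probabilities(b, mu)
            for name, got in (("eff", sp.efficacy), ("fut", sp.futility)):
                for j in range(2):
                    p = sim[name][j]
                    se = math.sqrt(max(p * (1 - p), 1e-9) / n)
                    assert abs(got[j] - p) < 3.5 * se


class TestExpectedConfirmatorySS:
    def test_single_stage_is_constant(self, conf_top_single):
        b = triangular_boundaries(conf_top_single)
        for mu in (0.0, 0.2):
            assert expected_confirmatory_ss(b, mu) == pytest.approx(
                2 * b.n_per_stage, rel=1e-12
            )

    def test_large_effect_stops_at_first_analysis(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs)
        assert expected_confirmatory_ss(b, 5.0) == pytest.approx(b.stage_ss[0], rel=1e-6)

    def test_sequential_stopping_saves_patients_at_delta(self, conf_top_gs):
        b = triangular_boundaries(conf_top_gs)
        assert expected_confirmatory_ss(b, 0.25) < 2 * single_stage_n2(0.25, 0.025, 0.1)


class TestEssTopGroupseq:
    def test_one_stage_reproduces_single_stage_ess(self, prior_ref, conf_top_single):
        conf_j1 = ConfirmatorySpec(delta=0.25, J=1, rule="top-treatment")
        for K, n1, c1 in [(1, 16, 0.814), (9, 22, -0.429)]:
            d = ScreeningDesign(K, n1, c1)
            gs = ess_top_groupseq(d, prior_ref, conf_j1)
            ss = ess_top_single(d, prior_ref, conf_top_single)
            assert gs.ess == pytest.approx(ss.ess, rel=1e-8)

    def test_two_stage_beats_single_stage_at_same_design(self, prior_ref,
                                                         conf_top_single, conf_top_gs):
        for K, n1, c1 in [(1, 8, 0.766), (4, 16, 0.223), (8, 14, -0.334)]:
            d = ScreeningDesign(K, n1, c1)
            gs = ess_top_groupseq(d, prior_ref, conf_top_gs)
            ss = ess_top_single(d, prior_ref, conf_top_single)
            assert gs.ess < ss.ess

    def test_decomposition_against_program_simulation(self, prior_ref, conf_top_gs):
        # full-program oracle: screen, select, run the two-stage trial
        K, n1, c1 = 1, 8, 0.766
        res = ess_top_groupseq(ScreeningDesign(K, n1, c1), prior_ref, conf_top_gs)
        b = triangular_boundaries(conf_top_gs)
        g = b.n_per_stage
        rng = np.random.default_rng(31)
        n = 4_000_000
        mu = rng.normal(0, 0.1, size=n)
        x1 = mu + rng.standard_normal(n) / math.sqrt(n1)
        x0 = rng.standard_normal(n) / math.sqrt(n1)
        sel = (x1 - x0) * math.sqrt(n1 / 2) > c1
        mus = mu[sel]
        m = mus.size
        e = rng.standard_normal((m, 2))
        f = rng.standard_normal((m, 2))
        z1 = mus * math.sqrt(g / 2) + (e[:, 0] - f[:, 0]) / math.sqrt(2)
        z2 = mus * math.sqrt(g) + (e.sum(1) - f.sum(1)) / 2
        s1e = z1 >= b.efficacy[0]
        cont = ~s1e & (z1 > b.futility[0])
        succ = s1e | (cont & (z2 >= b.efficacy[1]))
        ss = np.full(n, (K + 1) * n1, dtype=float)
        ss[sel] += np.where(cont, 2 * 2 * g, 2 * g)
        p = succ.sum() / n
        ess_mc = ss.mean() / p
        se = ess_mc / math.sqrt(succ.sum())
        assert abs(res.ess - ess_mc) < 3 * se


class TestMamsTriangularDesign:
    def test_one_arm_matches_two_arm_design(self, conf_top_gs):
        a = mams_triangular_design(1, conf_top_gs)
        b = triangular_boundaries(conf_top_gs)
        np.testing.assert_allclose(a.efficacy, b.efficacy, rtol=1e-9)
        assert a.n_per_stage == pytest.approx(b.n_per_stage, rel=1e-9)

    def test_single_stage_reduces_to_dunnett(self):
        from screenopt import dunnett_c2, multiarm_n2

        conf = ConfirmatorySpec(delta=0.25, J=1, rule="all-interesting")
        b = mams_triangular_design(3, conf)
        assert b.efficacy[0] == pytest.approx(dunnett_c2(3, 0.025), abs=1e-9)
        assert b.n_per_stage == pytest.approx(multiarm_n2(3, 0.25, 0.025, 0.1), rel=1e-9)

    def test_two_arm_mams_fwer_by_simulation(self):
        conf = ConfirmatorySpec(delta=0.25, J=2, rule="all-interesting")
        b = mams_triangular_design(2, conf)
        rng = np.random.default_rng(77)
        n = 4_000_000
        e = rng.standard_normal((n, 2, 2))  # arm x stage increments
        f = rng.standard_normal((n, 2))    # control increments
        z1 = (e[:, :, 0] - f[:, [0]]) / math.sqrt(2)
        z2 = (e.sum(axis=2) - f.sum(axis=1, keepdims=True)) / 2
        # non-binding: any arm ever over an efficacy bound
        cross = (z1 >= b.efficacy[0]) | (z2 >= b.efficacy[1])
        fwer = cross.any(axis=1).mean()
        se = math.sqrt(0.025 * 0.975 / n)
        assert abs(fwer - 0.025) < 3.5 * se
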