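"""Likelihood correctness against hand-expanded oracles, fitting, reporting.

The oracle below evaluates the Poisson-N integrated likelihood by direct
enumeration (explicit loops over mask points, detectors, occasions and sex
classes, scalar math only) and is kept independent of the package's
factored evaluation path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scrdens as sd
from scrdens.likelihood import LikelihoodContext, default_start


def oracle_loglik(theta, y, mask_pts, cell_area, trap_xy, behavior=None,
                  sex=None, sex_on_sigma=False):
    """Direct enumeration of the integrated SCR likelihood (scalar math).

    theta layout: [log D, logit g0, (behaviour effect), log sigma,
    (sigma sex effect), (logit psi)] matching the package's ordering for
    the specs exercised here.
    """
    n, J, K = y.shape
    M = len(mask_pts)
    pos = 0
    logD = theta[pos]; pos += 1
    b_g0 = theta[pos]; pos += 1
    b_beh = 0.0
    if behavior is not None:
        b_beh = theta[pos]; pos += 1
    b_sig = theta[pos]; pos += 1
    b_sig_sex = 0.0
    if sex_on_sigma:
        b_sig_sex = theta[pos]; pos += 1
    psi = None
    if sex is not None:
        psi = 1.0 / (1.0 + math.exp(-theta[pos])); pos += 1

    d = math.exp(logD) / 100.0

    def invlogit(x):
        return 1.0 / (1.0 + math.exp(-x))

    def p_ijk(m, j, k, zval, cls):
        sigma = math.exp(b_sig + (b_sig_sex if (sex_on_sigma and cls == 1) else 0.0))
        g0 = invlogit(b_g0 + b_beh * zval)
        dd = math.hypot(mask_pts[m][0] - trap_xy[j][0], mask_pts[m][1] - trap_xy[j][1])
        return g0 * math.exp(-dd * dd / (2 * sigma * sigma))

    if behavior is not None:
        z = np.zeros_like(y)
        for i in range(n):
            for j in range(J):
                for k in range(K):
                    if behavior == "bk":
                        z[i, j, k] = int(y[i, j, :k].any())
                    elif behavior == "b":
                        z[i, j, k] = int(y[i, :, :k].any())
                    else:
                        z[i, j, k] = int(y[i, j, k - 1]) if k else 0
    else:
        z = np.zeros_like(y)

    classes = [0, 1] if (sex is not None) else [None]
    # expected number detected
    Lam = 0.0
    for cls in classes:
        w = 1.0 if cls is None else (psi if cls == 0 else 1 - psi)
        for m in range(M):
            surv = 1.0
            for j in range(J):
                for k in range(K):
                    surv *= 1.0 - p_ijk(m, j, k, 0, cls)
            Lam += w * d * cell_area * (1.0 - surv)
    lnL = -Lam - math.lgamma(n + 1)
    for i in range(n):
        def hist_sum(cls):
            tot = 0.0
            for m in range(M):
                pr = 1.0
                for j in range(J):
                    for k in range(K):
                        p = p_ijk(m, j, k, z[i, j, k], cls)
                        pr *= p if y[i, j, k] else (1.0 - p)
                tot += pr
            return cell_area * tot
        if sex is None:
            contrib = hist_sum(None)
        elif sex[i] == "F":
            contrib = psi * hist_sum(0)
        elif sex[i] == "M":
            contrib = (1 - psi) * hist_sum(1)
        else:
            contrib = psi * hist_sum(0) + (1 - psi) * hist_sum(1)
        lnL += math.log(d) + math.log(contrib)
    return lnL


def _tiny_instance():
    traps = sd.TrapArray(["T1", "T2"], np.array([[0.0, 0.0], [4.0, 0.0]]))
    mask_pts = np.array([[-2.0, -1.0], [1.0, 2.0], [3.0, 1.0], [6.0, -2.0]])
    mask = sd.HabitatMask(mask_pts, cell_area=9.0, buffer=5.0, nx=2, ny=2,
                          spacing=(3.0, 3.0))
    y = np.zeros((2, 2, 2), dtype=np.uint8)
    y[0, 0, 0] = 1
    y[0, 1, 1] = 1
    y[1, 1, 1] = 1
    return traps, mask, y


class TestPdot:
    def test_single_detector_single_occasion(self):
        assert sd.p_dot(np.array([0.3]), n_occasions=1) == pytest.approx(0.3)

    def test_certain_detection(self):
        assert sd.p_dot(np.array([1.0, 0.1]), n_occasions=2) == pytest.approx(1.0)

    def test_two_by_two_expansion(self):
        p = np.array([[0.1, 0.25], [0.05, 0.4]])  # (J=2, K=2)
        expect = 1 - (1 - 0.1) * (1 - 0.25) * (1 - 0.05) * (1 - 0.4)
        assert sd.p_dot(p) == pytest.approx(expect, abs=1e-15)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_product_expansion(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 0.9, size=(int(r.integers(1, 5)), int(r.integers(1, 4))))
        expect = 1.0 - np.prod(1.0 - p)
        assert sd.p_dot(p) == pytest.approx(expect, abs=1e-12)


class TestLikelihoodOracle:
    def test_null_model_matches_hand_expansion(self):
        traps, mask, y = _tiny_instance()
        data = sd.CaptureData(["a", "b"], y)
        theta = np.array([np.log(2.3), -1.1, np.log(2.5)])
        got = -sd.neg_loglik(theta, sd.ModelSpec(), data, traps, mask)
        want = oracle_loglik(theta, y, mask.points, mask.cell_area, traps.xy)
        assert got == pytest.approx(want, abs=1e-10)

    def test_bk_model_matches_hand_expansion(self):
        traps, mask, y = _tiny_instance()
        data = sd.CaptureData(["a", "b"], y)
        theta = np.array([np.log(1.4), -0.7, 0.9, np.log(3.1)])
        spec = sd.ModelSpec(("intercept", "bk"))
        got = -sd.neg_loglik(theta, spec, data, traps, mask)
        want = oracle_loglik(theta, y, mask.points, mask.cell_area, traps.xy,
                             behavior="bk")
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("kind", ["b", "Bk"])
    def test_other_behaviours_match_hand_expansion(self, kind):
        traps, mask, y = _tiny_instance()
        y = y.copy()
        y[1, 0, 0] = 1  # extra detection so b/Bk states differ
        data = sd.CaptureData(["a", "b"], y)
        theta = np.array([np.log(1.4), -0.4, -0.6, np.log(2.2)])
        spec = sd.ModelSpec(("intercept", kind))
        got = -sd.neg_loglik(theta, spec, data, traps, mask)
        want = oracle_loglik(theta, y, mask.points, mask.cell_area, traps.xy,
                             behavior=kind)
        assert got == pytest.approx(want, abs=1e-10)

    def test_sex_mixture_matches_hand_expansion(self):
        traps, mask, y = _tiny_instance()
        data = sd.CaptureData(["a", "b"], y, sex=np.array(["F", "U"], dtype=object))
        theta = np.array([np.log(1.8), -1.3, np.log(2.0), 0.5, 0.3])
        spec = sd.ModelSpec(("intercept",), ("intercept", "sex"))
        got = -sd.neg_loglik(theta, spec, data, traps, mask)
        want = oracle_loglik(theta, y, mask.points, mask.cell_area, traps.xy,
                             sex=["F", "U"], sex_on_sigma=True)
        assert got == pytest.approx(want, abs=1e-10)

    def test_empty_data_gives_minus_lambda(self):
        traps, mask, _ = _tiny_instance()
        data = sd.CaptureData([], np.zeros((0, 2, 2), dtype=np.uint8))
        theta = np.array([np.log(0.9), -1.5, np.log(2.0)])
        got = -sd.neg_loglik(theta, sd.ModelSpec(), data, traps, mask)
        want = oracle_loglik(theta, data.y, mask.points, mask.cell_area, traps.xy)
        assert got == pytest.approx(want, abs=1e-12)
        assert got < 0  # lnL = -Lambda

    def test_invariant_under_mask_permutation(self):
        traps, mask, y = _tiny_instance()
        data = sd.CaptureData(["a", "b"], y)
        theta = np.array([np.log(1.1), -1.0, np.log(2.0)])
        f0 = sd.neg_loglik(theta, sd.ModelSpec(), data, traps, mask)
        perm = sd.HabitatMask(mask.points[::-1], mask.cell_area, mask.buffer,
                              mask.nx, mask.ny, mask.spacing)
        f1 = sd.neg_loglik(theta, sd.ModelSpec(), data, traps, perm)
        assert f0 == pytest.approx(f1, abs=1e-12)

    def test_cutoff_sparsification_negligible_error(self, small_array_traps,
                                                    small_mask, small_sim):
        theta = np.array([np.log(8.0), -1.7, np.log(2.5)])
        dense = LikelihoodContext(sd.ModelSpec(), small_sim, small_array_traps,
                                  small_mask)
        spar = LikelihoodContext(sd.ModelSpec(), small_sim, small_array_traps,
                                 small_mask, cutoff=6 * 2.5)
        assert spar.neg_loglik(theta) == pytest.approx(dense.neg_loglik(theta),
                                                       abs=1e-3)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(
            self, small_array_traps, small_mask, small_sim):
        from scipy.optimize import approx_fprime
        for cutoff in (None, 15.0):
            ctx = LikelihoodContext(sd.ModelSpec(), small_sim, small_array_traps,
                                    small_mask, cutoff=cutoff)
            theta = np.array([np.log(6.0), -1.5, np.log(3.0)])
            f, g = ctx.neg_loglik_grad(theta)
            assert f == pytest.approx(ctx.neg_loglik(theta), rel=1e-12)
            g_fd = approx_fprime(theta, ctx.neg_loglik, 1e-6)
            np.testing.assert_allclose(g, g_fd, rtol=2e-4, atol=2e-4)


class TestFit:
    def test_parameter_recovery_within_3se(self, small_array_traps, small_mask,
                                           small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        assert fit.converged
        for name, truth in (("D", 8.0), ("g0", 0.15), ("sigma", 2.5)):
            row = fit.real(name)
            assert abs(row["estimate"] - truth) < 3 * row["se"], (name, dict(row))

    def test_refit_from_mle_is_fixed_point(self, small_array_traps, small_mask,
                                           small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        refit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps,
                           small_mask, start=fit.beta)
        assert refit.lnL == pytest.approx(fit.lnL, abs=1e-6)

    def test_nested_model_likelihood_ordering(self, small_array_traps,
                                              small_mask, small_sim):
        null = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        bk = sd.fit_scr(sd.ModelSpec(("intercept", "bk")), small_sim,
                        small_array_traps, small_mask)
        assert bk.lnL >= null.lnL - 1e-6

    def test_bk_response_recovered(self, small_array_traps, small_mask,
                                   small_sim_bk):
        fit = sd.fit_scr(sd.ModelSpec(("intercept", "bk")), small_sim_bk,
                         small_array_traps, small_mask)
        assert fit.converged
        assert fit.real("g0.bk1")["estimate"] > fit.real("g0.bk0")["estimate"]

    def test_mask_refinement_converges(self, small_array_traps, small_sim):
        lnls = []
        for nx in (16, 32, 48):
            mask = sd.build_mask(small_array_traps, 12.0, nx=nx)
            fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, mask)
            lnls.append(fit.lnL)
        assert abs(lnls[2] - lnls[1]) < abs(lnls[1] - lnls[0])

    def test_default_start_reasonable(self, small_array_traps, small_mask,
                                      small_sim):
        x0 = default_start(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        assert np.all(np.isfinite(x0))
        ctx = LikelihoodContext(sd.ModelSpec(), small_sim, small_array_traps,
                                small_mask)
        assert np.isfinite(ctx.neg_loglik(x0))


class TestDerived:
    def test_ci_degenerate_se(self):
        assert sd.density_ci(1.7, 0.0) == (1.7, 1.7)

    def test_ci_positive_bounds(self, rng):
        for _ in range(20):
            D = float(rng.uniform(0.01, 10))
            se = float(rng.uniform(0, 5))
            lo, hi = sd.density_ci(D, se)
            assert 0 < lo <= D <= hi

    def test_expected_N_linearity(self, small_array_traps, small_mask, small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        e1, s1, _ = sd.expected_N(fit, 1000.0)
        e2, s2, _ = sd.expected_N(fit, 3000.0)
        assert e2 == pytest.approx(3 * e1)
        assert s2 == pytest.approx(3 * s1)

    def test_expected_N_simple_arithmetic(self, small_array_traps, small_mask,
                                          small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        est, _, _ = sd.expected_N(fit, 100.0)
        assert est == pytest.approx(fit.D_hat)

    def test_expected_N_rejects_bad_area(self, small_array_traps, small_mask,
                                         small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        with pytest.raises(ValueError):
            sd.expected_N(fit, -5.0)


class TestCheckBuffer:
    def test_factor_one_no_change(self, small_array_traps, small_mask, small_sim):
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, small_mask)
        tab = sd.check_buffer(fit, factors=(1.0,), refit=True)
        assert abs(tab["rel_change_D"].iloc[0]) < 1e-4
        assert not tab["exceeds_tol"].iloc[0]

    def test_generous_buffer_saturated(self, small_array_traps, small_sim):
        # buffer ~5 sigma: enlarging it should not move D-hat
        mask = sd.build_mask(small_array_traps, 12.0, nx=32)
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, mask)
        tab = sd.check_buffer(fit, factors=(1.5,), refit=True)
        assert abs(tab["rel_change_D"].iloc[0]) < 0.01

    def test_starved_buffer_flagged(self, small_array_traps, small_sim):
        # buffer below 2 sigma biases the fit; the diagnostic must flag it
        starved = sd.build_mask(small_array_traps, 4.0, nx=24)
        fit = sd.fit_scr(sd.ModelSpec(), small_sim, small_array_traps, starved)
        tab = sd.check_buffer(fit, factors=(2.5,), refit=True)
        assert tab["exceeds_tol"].iloc[0]
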