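import math

import numpy as np
import pytest

from dnaelastic import (AnalysisWindow, constants_from_fluctuations,
                        crookedness_stiffness, effective_from_constants,
                        fep_weights, fit_force_response, force_dependence,
                        step_parameter_slope, stretch_modulus_effective)
from dnaelastic.constants import kbt
from dnaelastic.elasticity import ElasticConstants
from dnaelastic.observables import ObservableSeries, compute_observables
from dnaelastic.reweight import WeightedEnsemble
from dnaelastic.synthgen import MicroParams, gen_micro_trajectory

FORCES = [0.0, 1.0, 5.0, 10.0, 15.0, 20.0]


class TestFitForceResponse:
    def test_exact_line_zero_error(self):
        pts = [(F, 2.0 + 0.5 * F, 0.0) for F in FORCES]
        fit = fit_force_response(pts, seed=0)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(2.0, rel=1e-12)
        assert fit.delta_slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_point_errors_inflate_delta_only(self):
        pts = [(F, 2.0 + 0.5 * F, 0.1) for F in FORCES]
        fit = fit_force_response(pts, seed=0)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.delta_slope > 0

    def test_recovers_known_slope_within_3delta(self):
        rng = np.random.default_rng(5)
        pts = [(F, 0.003 * F + rng.normal(0, 1e-4), 1e-4)
               for F in (1.0, 5.0, 10.0, 15.0, 20.0)]
        fit = fit_force_response(pts, seed=1)
        assert abs(fit.slope - 0.003) < 3 * fit.delta_slope

    def test_too_few_or_singular(self):
        with pytest.raises(ValueError):
            fit_force_response([(0, 1, 0), (1, 2, 0)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_force_response([(5, 1, 0), (5, 2, 0), (5, 3, 0)])


class TestStretchModulusEffective:
    def test_scalar_inversion(self):
        fit = fit_force_response([(F, 0.0028333 * F, 0.0) for F in FORCES])
        S, dS = stretch_modulus_effective(fit, L0=3.4)
        assert S == pytest.approx(1200.01, abs=0.5)

    def test_inverse_proportionality(self):
        f1 = fit_force_response([(F, 0.002 * F, 0.0) for F in FORCES])
        f2 = fit_force_response([(F, 0.004 * F, 0.0) for F in FORCES])
        S1, _ = stretch_modulus_effective(f1, 3.4)
        S2, _ = stretch_modulus_effective(f2, 3.4)
        assert S1 == pytest.approx(2 * S2, rel=1e-9)

    def test_negative_slope_unphysical(self):
        fit = fit_force_response([(F, -0.001 * F, 0.0) for F in FORCES])
        with pytest.raises(ValueError, match="unphysical"):
            stretch_modulus_effective(fit, 3.4)


class TestCrookednessStiffness:
    def test_ratio(self):
        fit = fit_force_response([(F, 0.95 + 9.5e-5 * F, 0.0) for F in FORCES])
        c0, k, dc0, dk = crookedness_stiffness(fit)
        assert c0 == pytest.approx(0.95, rel=1e-9)
        assert k == pytest.approx(10000.0, rel=1e-6)

    def test_rigid_limit_sentinel(self):
        fit = fit_force_response([(F, 0.95, 0.0) for F in FORCES])
        c0, k, _, dk = crookedness_stiffness(fit)
        assert k == math.inf and dk == math.inf

    def test_impossible_intercept(self):
        fit = fit_force_response([(F, 1.05 + 1e-4 * F, 0.0) for F in FORCES])
        with pytest.raises(ValueError, match="c0"):
            crookedness_stiffness(fit)


def _gaussian_ensemble(S, C, g, L0, T, n, seed, F=0.0):
    kT = kbt(T)
    K = np.array([[S, g], [g, C]])
    Sigma = kT * L0 * np.linalg.inv(K)
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal([L0, 6.0], Sigma, size=n)
    s = ObservableSeries(L=x[:, 0], theta=x[:, 1],
                         cosbeta=np.full(n, 0.95),
                         beta=np.full(n, np.arccos(0.95)),
                         usum=x[:, 0] / 0.95, force=F, temperature=T)
    return WeightedEnsemble(s, np.ones(n), float(n), F)


class TestConstantsFromFluctuations:
    def test_forward_map_identity(self):
        """Exact forward covariance -> exact constants (2x2 inversion)."""
        S, C, g, L0, T = 1200.0, 430.0, -100.0, 3.4, 300.0
        kT_L0 = kbt(T) * L0
        K = np.array([[S, g], [g, C]])
        Sigma = kT_L0 * np.linalg.inv(K)
        # build an ensemble with *exactly* this sample covariance
        n = 4
        base = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        base -= base.mean(axis=0)
        cov0 = base.T @ base / n
        Lchol = np.linalg.cholesky(Sigma) @ np.linalg.inv(np.linalg.cholesky(cov0))
        x = base @ Lchol.T
        s = ObservableSeries(L=L0 + x[:, 0], theta=6.0 + x[:, 1],
                             cosbeta=np.full(n, 0.9), beta=np.full(n, 0.45),
                             usum=(L0 + x[:, 0]) / 0.9, force=0.0,
                             temperature=T)
        ens = WeightedEnsemble(s, np.ones(n), float(n), 0.0)
        ec = constants_from_fluctuations(ens, L0, errors="none")
        assert ec.S == pytest.approx(S, rel=1e-10)
        assert ec.C == pytest.approx(C, rel=1e-10)
        assert ec.g == pytest.approx(g, rel=1e-10)

    def test_reference_covariance_values(self):
        # the covariance implied by (S, C, g) = (1200, 430, -100) at 300 K
        kT_L0 = kbt(300.0) * 3.4
        K = np.array([[1200.0, -100.0], [-100.0, 430.0]])
        Sigma = kT_L0 * np.linalg.inv(K)
        assert Sigma[0, 0] == pytest.approx(0.0119674, abs=2e-6)
        assert Sigma[1, 1] == pytest.approx(0.0333972, abs=2e-6)
        assert Sigma[0, 1] == pytest.approx(0.00278310, abs=2e-7)

    def test_decoupled_limit(self):
        n = 2000
        rng = np.random.default_rng(0)
        L = 3.4 + rng.normal(0, 0.1, n)
        th = 6.0 + rng.normal(0, 0.18, n)
        s = ObservableSeries(L=L, theta=th, cosbeta=np.full(n, 0.95),
                             beta=np.full(n, 0.3), usum=L / 0.95,
                             force=0.0, temperature=300.0)
        ens = WeightedEnsemble(s, np.ones(n), float(n), 0.0)
        ec = constants_from_fluctuations(ens, 3.4, errors="none")
        varL = np.var(L)
        vart = np.var(th)
        covLt = np.cov(L, th, bias=True)[0, 1]
        kT_L0 = kbt(300.0) * 3.4
        det = varL * vart - covLt ** 2
        assert ec.S == pytest.approx(kT_L0 * vart / det, rel=1e-9)
        assert ec.g == pytest.approx(-kT_L0 * covLt / det, rel=1e-9)

    def test_sampling_recovery_within_3pc(self):
        ens = _gaussian_ensemble(1200.0, 430.0, -100.0, 3.4, 300.0,
                                 n=200_000, seed=1)
        ec = constants_from_fluctuations(ens, 3.4, errors="none")
        assert ec.S == pytest.approx(1200.0, rel=0.03)
        assert ec.C == pytest.approx(430.0, rel=0.03)
        assert ec.g == pytest.approx(-100.0, rel=0.05)

    def test_degenerate_fluctuations_rejected(self):
        n = 100
        L = 3.4 + np.linspace(-0.1, 0.1, n)
        th = 6.0 + 2.0 * (L - 3.4)    # perfectly correlated
        s = ObservableSeries(L=L, theta=th, cosbeta=np.full(n, 0.95),
                             beta=np.full(n, 0.3), usum=L / 0.95,
                             force=0.0, temperature=300.0)
        ens = WeightedEnsemble(s, np.ones(n), float(n), 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            constants_from_fluctuations(ens, 3.4, errors="none")


class TestEffectiveFromConstants:
    def test_no_coupling(self):
        assert effective_from_constants(1200.0, 430.0, 0.0) == 1200.0

    def test_scalar_value(self):
        assert effective_from_constants(1200.0, 430.0, -100.0) == \
            pytest.approx(1176.74, abs=0.01)

    def test_even_in_g(self):
        assert effective_from_constants(1200.0, 430.0, 100.0) == \
            effective_from_constants(1200.0, 430.0, -100.0)

    def test_invalid_C(self):
        with pytest.raises(ValueError):
            effective_from_constants(1200.0, -1.0, 10.0)


class TestForceDependence:
    def _constants(self, Sfun, Cfun, gfun):
        out = []
        for F in FORCES:
            out.append(ElasticConstants(
                F=F, S=Sfun(F), C=Cfun(F), g=gfun(F),
                S_eff=Sfun(F) - gfun(F) ** 2 / Cfun(F), L0=3.4, theta0=6.0))
        return out

    def test_exact_stiffening_slope(self):
        cs = self._constants(lambda F: 1000 + 10 * F, lambda F: 430.0,
                             lambda F: -100.0)
        fit = force_dependence(cs, "S")
        assert fit.slope == pytest.approx(10.0, rel=1e-9)

    def test_flat_twist_modulus(self):
        cs = self._constants(lambda F: 1000.0, lambda F: 430.0, lambda F: -100.0)
        fit = force_dependence(cs, "C")
        assert abs(fit.slope) <= max(fit.delta_slope, 1e-9)


class TestStepParameterSlope:
    def _study(self, n=4000, seed=0):
        p = MicroParams(n_frames=n, seed=seed, phi=0.0)
        trajs = [gen_micro_trajectory(p, F) for F in FORCES]
        series = [compute_observables(t, AnalysisWindow(0, t.n_bp - 1))
                  for t in trajs]
        ens = [fep_weights(s) for s in series]
        return p, trajs, ens

    def test_u_recovery(self):
        p, trajs, ens = self._study(n=20_000, seed=3)
        w = AnalysisWindow(0, trajs[0].n_bp - 1)
        res = step_parameter_slope(ens, trajs, "u", w, seed=4)
        steps = p.step_types()
        for j, st in enumerate(steps):
            assert abs(res.u0[j] - p.u0[st]) < max(3 * res.du0[j], 1e-3)
            assert abs(res.k[j] - p.k[st]) < 3 * res.dk[j]

    def test_slide_slope_recovery(self):
        p, trajs, ens = self._study(n=20_000, seed=6)
        w = AnalysisWindow(0, trajs[0].n_bp - 1)
        res = step_parameter_slope(ens, trajs, "slide", w, seed=7)
        for f in res.fits:
            assert abs(f.slope - p.slide_slope) < 3 * f.delta_slope
            assert abs(f.intercept - p.slide0) < 3 * f.delta_intercept

    def test_rigid_step_infinite_k(self):
        import dnaelastic.elasticity as el
        fits = [el.fit_force_response([(F, 0.34, 0.0) for F in FORCES])]
        # direct check of the sentinel logic on a rigid (flat) response
        assert fits[0].slope == pytest.approx(0.0, abs=1e-15)

    def test_exact_ratio(self):
        # <u>_F = u0 (1 + F/k) with u0=0.34, k=6800 -> slope 5e-5
        pts = [(F, 0.34 * (1 + F / 6800.0), 0.0) for F in FORCES]
        from dnaelastic.elasticity import fit_force_response
        fit = fit_force_response(pts)
        assert fit.slope == pytest.approx(5e-5, rel=1e-9)
        assert fit.intercept / fit.slope == pytest.approx(6800.0, rel=1e-9)
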