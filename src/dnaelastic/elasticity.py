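"""Elastic constants of the duplex from force-response fits and fluctuations.

Two complementary routes are implemented.

*Slope route.*  Fitting the reweighted averages across forces:
``<dL>_F = L0 F / S_eff`` gives the effective stretch modulus, and
``<cos b>_F = c0 (1 + F / k_beta)`` the crookedness stiffness.

*Fluctuation route.*  At each force the weighted covariance matrix Sigma of
(L, theta) yields the stiffness matrix of the harmonic extension-torsion
energy, ``K = kBT * L0 * Sigma^{-1}``, i.e.

    S = kBT L0 Var(theta) / det,   C = kBT L0 Var(L) / det,
    g = -kBT L0 Cov(L, theta) / det,      det = Var(L) Var(theta) - Cov^2,

with the effective modulus following as ``S_eff = S - g^2 / C`` (minimising
the energy over the torsion at fixed force).  Linear fits of S, C, g versus
force give the stiffening slopes dS/dF, dC/dF, dg/dF.

Fit errors follow a two-channel protocol: ``delta_ave`` from the standard
least-squares covariance and ``delta_ind`` from seeded Monte-Carlo resamples
of the points perturbed by their individual error bars; the two are combined
in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import kbt
from .reweight import WeightedEnsemble, weighted_moments
from .trajio import AnalysisWindow, HelicalTrajectory
from .uncertainty import block_bootstrap_error, combine_fit_errors

__all__ = [
    "LinearFit", "ElasticConstants", "StepSlopes",
    "fit_force_response", "stretch_modulus_effective", "crookedness_stiffness",
    "constants_from_fluctuations", "effective_from_constants",
    "force_dependence", "step_parameter_slope",
]


@dataclass
class LinearFit:
    """Unweighted least-squares line with two-channel errors.

    ``mc_cov`` is the 2x2 covariance of (slope, intercept) over the
    Monte-Carlo point-resampling channel; it is kept so downstream ratios
    (e.g. intercept/slope) can propagate the sampled correlation.
    """

    slope: float
    intercept: float
    delta_slope: float
    delta_intercept: float
    r2: float
    delta_slope_ave: float = 0.0
    delta_intercept_ave: float = 0.0
    mc_cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        if self.delta_slope < 0 or self.delta_intercept < 0:
            raise ValueError("fit errors must be non-negative")

    def predict(self, x: float | np.ndarray):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ElasticConstants:
    """Stretch modulus S (pN), twist modulus C (pN nm^2), twist-stretch
    coupling g (pN nm) and effective modulus S_eff (pN) at one force."""

    F: float
    S: float
    C: float
    g: float
    S_eff: float
    L0: float
    theta0: float
    dS: float = 0.0
    dC: float = 0.0
    dg: float = 0.0
    dS_eff: float = 0.0
    positive_definite: bool = True

    def __post_init__(self) -> None:
        if self.S <= 0 or self.C <= 0 or self.S * self.C - self.g ** 2 <= 0:
            # keep the record but flag it: a non-positive-definite stiffness
            # is diagnostic output, not a usable elastic description
            self.positive_definite = False


def fit_force_response(points: list[tuple[float, float, float]],
                       n_mc: int = 1000, seed: int = 0) -> LinearFit:
    """Fit ``y = intercept + slope * F`` to (F, y, dy) points.

    The line itself is the unweighted least-squares solution; ``dy`` enters
    only through the Monte-Carlo indeterminacy channel (points re-drawn as
    ``N(y, dy)``, refit, spread of the coefficients over ``n_mc`` seeded
    resamples), combined in quadrature with the least-squares channel.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (F, y, dy) triples")
    F, y, dy = pts.T
    if len(F) < 3:
        raise ValueError("need at least 3 points for the two-channel error fit")
    if np.any(dy < 0):
        raise ValueError("point errors dy must be non-negative")
    if np.ptp(F) == 0:
        raise np.linalg.LinAlgError("all forces identical: singular design")
    X = np.column_stack([F, np.ones_like(F)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = beta
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = len(F) - 2
    sigma2 = rss / dof
    cov_ave = sigma2 * np.linalg.inv(X.T @ X)
    d_slope_ave = math.sqrt(max(cov_ave[0, 0], 0.0))
    d_int_ave = math.sqrt(max(cov_ave[1, 1], 0.0))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    mc_cov = np.zeros((2, 2))
    d_slope_ind = d_int_ind = 0.0
    if np.any(dy > 0):
        rng = np.random.default_rng(seed)
        ys = y + rng.standard_normal((n_mc, len(y))) * dy
        # closed-form lstsq for all resamples at once
        betas = np.linalg.solve(X.T @ X, X.T @ ys.T).T    # (n_mc, 2)
        mc_cov = np.cov(betas.T)
        d_slope_ind = math.sqrt(mc_cov[0, 0])
        d_int_ind = math.sqrt(mc_cov[1, 1])
    return LinearFit(
        slope=float(slope), intercept=float(intercept),
        delta_slope=combine_fit_errors(d_slope_ave, d_slope_ind),
        delta_intercept=combine_fit_errors(d_int_ave, d_int_ind),
        r2=r2, delta_slope_ave=d_slope_ave, delta_intercept_ave=d_int_ave,
        mc_cov=mc_cov,
    )


def stretch_modulus_effective(fit: LinearFit, L0: float, dL0: float = 0.0
                              ) -> tuple[float, float]:
    """Effective stretch modulus from the <dL>_F slope: S_eff = L0 / slope."""
    if fit.slope <= 0:
        raise ValueError(
            f"unphysical force response: slope {fit.slope:.4g} nm/pN <= 0 "
            "(extension must grow with pulling force)"
        )
    S_eff = L0 / fit.slope
    rel2 = (fit.delta_slope / fit.slope) ** 2
    if L0 > 0 and dL0:
        rel2 += (dL0 / L0) ** 2
    return float(S_eff), float(S_eff * math.sqrt(rel2))


def crookedness_stiffness(fit: LinearFit) -> tuple[float, float, float, float]:
    """(c0, k_beta, dc0, dk_beta) from the <cos b>_F = c0 (1 + F/k_beta) fit.

    ``c0`` is the zero-force extrapolation of <cos b> (must lie in (0, 1]);
    ``k_beta = c0 / slope``.  A zero slope is the rigid limit and returns an
    infinite stiffness sentinel.
    """
    c0 = fit.intercept
    if not (0.0 < c0 <= 1.0):
        raise ValueError(f"intercept c0 = {c0:.4g} outside (0, 1]: cos(beta) bound violated")
    tol = 1e-12 * abs(c0)   # slope below float noise = rigid limit
    if fit.slope < -tol:
        raise ValueError(
            f"negative <cos beta>_F slope ({fit.slope:.3g}/pN): crookedness "
            "must decrease (cos beta grow) under pulling"
        )
    if fit.slope <= tol:
        return float(c0), math.inf, float(fit.delta_intercept), math.inf
    k = c0 / fit.slope
    # delta_ave channel: independent first-order propagation
    rel_ave2 = (fit.delta_intercept_ave / c0) ** 2 + \
               (fit.delta_slope_ave / fit.slope) ** 2
    dk_ave = abs(k) * math.sqrt(rel_ave2)
    # delta_ind channel including the sampled slope-intercept covariance
    mc = fit.mc_cov
    rel_ind2 = mc[1, 1] / c0 ** 2 + mc[0, 0] / fit.slope ** 2 \
        - 2.0 * mc[0, 1] / (c0 * fit.slope)
    dk_ind = abs(k) * math.sqrt(max(rel_ind2, 0.0))
    return float(c0), float(k), float(fit.delta_intercept), \
        combine_fit_errors(dk_ave, dk_ind)


def effective_from_constants(S: float, C: float, g: float) -> float:
    """Closed form S_eff = S - g^2 / C (even in the sign of g)."""
    if C <= 0:
        raise ValueError(f"twist modulus must be positive, got C = {C}")
    return S - g ** 2 / C


def _fluctuation_map(VL: float, Vt: float, c: float, kT_L0: float
                     ) -> tuple[float, float, float, float]:
    det = VL * Vt - c * c
    if det <= 0:
        raise ValueError(
            f"degenerate (L, theta) fluctuations: det Sigma = {det:.3g} <= 0"
        )
    S = kT_L0 * Vt / det
    C = kT_L0 * VL / det
    g = -kT_L0 * c / det
    return S, C, g, det


def constants_from_fluctuations(ensemble: WeightedEnsemble, L0: float,
                                theta0: float | None = None,
                                errors: str = "block",
                                n_boot: int = 1000, seed: int = 0,
                                max_sizes: int = 400) -> ElasticConstants:
    """Elastic constants from the weighted (L, theta) covariance at one force.

    The stiffness matrix of the harmonic energy is ``kBT L0 Sigma^{-1}``;
    ``L0`` is the *zero-force* equilibrium length (the unstressed length
    fixed by the energy expansion), passed in even when the ensemble is at
    F > 0.  Errors propagate first-order from block-bootstrap errors of the
    three covariance entries (``errors="none"`` skips them).
    """
    s = ensemble.series
    if np.ptp(s.L) == 0 or np.ptp(s.theta) == 0:
        raise ValueError("zero fluctuation in L or theta: constants undefined")
    means, cov = weighted_moments([s.L, s.theta], ensemble)
    VL, Vt, c = float(cov[0, 0]), float(cov[1, 1]), float(cov[0, 1])
    kT_L0 = kbt(s.temperature) * L0
    S, C, g, det = _fluctuation_map(VL, Vt, c, kT_L0)
    S_eff = effective_from_constants(S, C, g)

    dS = dC = dg = dS_eff = 0.0
    if errors == "block":
        eVL = block_bootstrap_error(s.L, ensemble, "variance",
                                    n_boot=n_boot, seed=seed, max_sizes=max_sizes).final_error
        eVt = block_bootstrap_error(s.theta, ensemble, "variance",
                                    n_boot=n_boot, seed=seed + 1, max_sizes=max_sizes).final_error
        ec = block_bootstrap_error(s.L, ensemble, "covariance", second=s.theta,
                                   n_boot=n_boot, seed=seed + 2, max_sizes=max_sizes).final_error
        # analytic partials of (S, C, g) wrt (VL, Vt, c)
        dS_d = np.array([-kT_L0 * Vt ** 2, -kT_L0 * c ** 2, 2 * kT_L0 * Vt * c]) / det ** 2
        dC_d = np.array([-kT_L0 * c ** 2, -kT_L0 * VL ** 2, 2 * kT_L0 * VL * c]) / det ** 2
        dg_d = np.array([kT_L0 * c * Vt, kT_L0 * c * VL, -kT_L0 * (VL * Vt + c * c)]) / det ** 2
        evec = np.array([eVL, eVt, ec])
        dS = float(np.sqrt(np.sum((dS_d * evec) ** 2)))
        dC = float(np.sqrt(np.sum((dC_d * evec) ** 2)))
        dg = float(np.sqrt(np.sum((dg_d * evec) ** 2)))
        # S_eff = S - g^2/C, chain rule through the same entries
        dSe_d = dS_d - (2 * g / C) * dg_d + (g / C) ** 2 * dC_d
        dS_eff = float(np.sqrt(np.sum((dSe_d * evec) ** 2)))
    elif errors != "none":
        raise ValueError("errors must be 'block' or 'none'")

    return ElasticConstants(
        F=ensemble.F, S=S, C=C, g=g, S_eff=S_eff, L0=L0,
        theta0=float(means[1]) if theta0 is None else theta0,
        dS=dS, dC=dC, dg=dg, dS_eff=dS_eff,
    )


def force_dependence(constants: list[ElasticConstants], which: str,
                     n_mc: int = 1000, seed: int = 0) -> LinearFit:
    """Linear fit of S, C or g versus force, e.g. S(F) = S0 + F dS/dF."""
    attr = {"S": ("S", "dS"), "C": ("C", "dC"), "g": ("g", "dg")}
    if which not in attr:
        raise ValueError("which must be 'S', 'C' or 'g'")
    v, dv = attr[which]
    pts = [(ec.F, getattr(ec, v), getattr(ec, dv)) for ec in constants]
    return fit_force_response(pts, n_mc=n_mc, seed=seed)


@dataclass
class StepSlopes:
    """Per-step force-response of one helical parameter.

    For the center-to-center distance ``u`` the fit is read as
    ``<u_i>_F = u0_i (1 + F / k_i)``, giving the per-step elastic constant
    ``k_i = u0_i / slope`` (infinite for a rigid step) and zero-force length
    ``u0_i = intercept``.
    """

    parameter: str
    step_index: np.ndarray
    fits: list[LinearFit]
    k: np.ndarray | None = None
    u0: np.ndarray | None = None
    dk: np.ndarray | None = None
    du0: np.ndarray | None = None


def _point_error(values: np.ndarray, ens: WeightedEnsemble, error_method: str,
                 n_boot: int, seed: int, max_sizes: int) -> float:
    if error_method == "block":
        return block_bootstrap_error(values, ens, "mean", n_boot=n_boot,
                                     seed=seed, max_sizes=max_sizes).final_error
    # ESS-corrected weighted standard error of the mean
    w = ens.weights
    m = np.sum(w * values) / np.sum(w)
    var = np.sum(w * (values - m) ** 2) / np.sum(w)
    return float(np.sqrt(var / ens.ess))


def step_parameter_slope(ensembles: list[WeightedEnsemble],
                         trajs: list[HelicalTrajectory],
                         parameter: str,
                         window: AnalysisWindow,
                         error_method: str = "sem",
                         n_boot: int = 200, seed: int = 0,
                         max_sizes: int = 200, n_mc: int = 1000) -> StepSlopes:
    """Per-step linear force response of a helical parameter.

    For every step in the window the FEP-weighted mean of the parameter is
    computed at each force and fitted against F.  ``error_method`` chooses
    the point-error estimator: "sem" (effective-sample-size corrected
    weighted SEM, cheap) or "block" (full block bootstrap).
    """
    if parameter not in ("slide", "rise", "twist", "u"):
        raise ValueError("parameter must be slide, rise, twist or u")
    if len(ensembles) != len(trajs):
        raise ValueError("one ensemble per trajectory required")
    for t in trajs:
        if getattr(t, parameter) is None:
            raise ValueError(f"trajectory at F={t.force} lacks {parameter}")
        window.check(t.n_bp)
    steps = np.arange(window.first, window.last)
    fits: list[LinearFit] = []
    for j, si in enumerate(steps):
        pts = []
        for i, (ens, t) in enumerate(zip(ensembles, trajs)):
            vals = getattr(t, parameter)[:, si]
            m = np.sum(ens.weights * vals) / np.sum(ens.weights)
            dy = _point_error(vals, ens, error_method, n_boot,
                              seed + 1000 * j + i, max_sizes)
            pts.append((t.force, float(m), dy))
        fits.append(fit_force_response(pts, n_mc=n_mc, seed=seed + j))
    result = StepSlopes(parameter=parameter, step_index=steps, fits=fits)
    if parameter == "u":
        k = np.empty(len(fits))
        dk = np.empty(len(fits))
        u0 = np.array([f.intercept for f in fits])
        du0 = np.array([f.delta_intercept for f in fits])
        for i, f in enumerate(fits):
            if f.slope <= 0:
                k[i], dk[i] = math.inf, math.inf
            else:
                k[i] = f.intercept / f.slope
                rel2 = (f.delta_intercept / f.intercept) ** 2 + \
                       (f.delta_slope / f.slope) ** 2
                dk[i] = abs(k[i]) * math.sqrt(rel2)
        result.k, result.u0, result.dk, result.du0 = k, u0, dk, du0
    return result
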