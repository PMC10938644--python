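"""Synthetic helical-parameter trajectories with known elastic ground truth.

No trajectory data are deposited with the study this package supports, so
every stage of the analysis is validated on generated ensembles whose
statistical structure matches what the estimators assume:

* :func:`gen_rod_trajectory` — the harmonic extension-torsion rod: (L, theta)
  drawn from the stationary Gaussian of the quadratic energy at force F
  (mean shift ``dL = F L0 C / (SC - g^2)``, ``dtheta = -F L0 g / (SC - g^2)``,
  covariance ``kBT L0 K^{-1}``), with AR(1) memory emulating the snapshot
  autocorrelation of MD output.
* :func:`gen_micro_trajectory` — the microstructure picture: per-step
  center-to-center distances responding as ``<u_i>_F = u0_i (1 + F/k_i)``
  with equipartition variance, and a fluctuating crookedness
  ``<cos b>_F = c0 (1 + F/k_beta)``, so the series-of-springs prediction has
  an exact synthetic realisation.
* :func:`gen_bend_series` — terminal-frame bending angles with variances
  ``Lbar / lp`` per mode, plus triads realising them.

The pulled anchor distance is modelled as ``d = L + eps`` with harmonic
noise eps; because the simulated ensemble conjugates the force to ``d``
rather than ``L``, eps acquires the tilt mean ``F sigma_d^2 / kBT`` under
the pulled ensemble, which is what makes the FEP weights non-uniform and
testable.  All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .constants import kbt
from .crookmodel import canonical_step
from .trajio import HelicalTrajectory

__all__ = [
    "RodParams", "MicroParams", "DEFAULT_STEP_K", "DEFAULT_STEP_U0",
    "POLY_XY_STEPS", "poly_xy_window_sequence", "RNG_SEQUENCE",
    "gen_rod_trajectory", "gen_micro_trajectory", "gen_bend_series",
]

#: default per-step elastic constants (pN); poly-AA is the stiff outlier
DEFAULT_STEP_K = {
    "AA": 9000.0, "AC": 6000.0, "AG": 7000.0, "AT": 5000.0, "CA": 4500.0,
    "CG": 5500.0, "GA": 6500.0, "GC": 6000.0, "GG": 4000.0, "TA": 4200.0,
}

#: default zero-force center-to-center distances (nm)
DEFAULT_STEP_U0 = {
    "AA": 0.335, "AC": 0.340, "AG": 0.342, "AT": 0.338, "CA": 0.345,
    "CG": 0.350, "GA": 0.340, "GC": 0.344, "GG": 0.352, "TA": 0.348,
}

#: the six repeats whose windows jointly cover the ten distinct steps
POLY_XY_STEPS = ("AA", "AC", "AG", "AT", "CG", "GG")

#: a 16-mer whose steps cover all ten distinct dinucleotide types,
#: standing in for a random sequence
RNG_SEQUENCE = "GCACATAAGAGGCGCG"


def poly_xy_window_sequence(xy: str, n_repeats: int = 5) -> str:
    """The analysis-window decamer of a poly-XY repeat, e.g. 'ACACACACAC'."""
    if len(xy) != 2:
        raise ValueError("xy must be a dinucleotide")
    return (xy * n_repeats)[: 2 * n_repeats]


def _rng_for(seed: int, force: float) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(round(force * 1000))])


def _ar1(rng: np.random.Generator, n: int, ncol: int, phi: float,
         chol: np.ndarray) -> np.ndarray:
    """Stationary AR(1) series, zero mean, stationary covariance chol@chol.T."""
    z = rng.standard_normal((n, ncol)) @ chol.T
    if phi == 0.0:
        return z
    z[1:] *= math.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], z, axis=0)


@dataclass
class RodParams:
    """Ground truth for the harmonic rod generator (paper-scale defaults)."""

    S: float = 1200.0          # pN
    C: float = 430.0           # pN nm^2
    g: float = -100.0          # pN nm
    L0: float = 3.4            # nm
    theta0: float = math.radians(343.0)   # rad
    T: float = 300.0           # K
    phi: float = 0.8           # AR(1) lag-1 correlation
    d_noise_sd: float = 0.1    # nm
    dSdF: float = 0.0          # optional built-in stiffening, pN/pN
    cosbeta0: float = 0.95     # constant crookedness of the rod
    lp_tau: float | None = None   # nm; attach bending triads when set
    lp_rho: float | None = None
    n_frames: int = 200_000
    seed: int = 0
    n_steps: int = 10

    def __post_init__(self) -> None:
        if self.S <= 0 or self.C <= 0 or self.S * self.C - self.g ** 2 <= 0:
            raise ValueError("stiffness matrix must be positive definite")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must be in [0, 1)")
        if not (0.0 < self.cosbeta0 <= 1.0):
            raise ValueError("cosbeta0 must be in (0, 1]")


def rod_mean_shift(p: RodParams, F: float) -> tuple[float, float]:
    """Analytic E(F) mean shifts (dL, dtheta) of the rod at force F."""
    S_F = p.S + p.dSdF * F
    det = S_F * p.C - p.g ** 2
    return F * p.L0 * p.C / det, -F * p.L0 * p.g / det


def gen_rod_trajectory(p: RodParams, F: float) -> HelicalTrajectory:
    """Sample the contour-length ensemble E(F) of the harmonic rod.

    The returned trajectory is the (already trimmed) analysis window:
    ``n_steps + 1`` base pairs, L spread over equal rises, theta over equal
    twists, ``u = rise / cosbeta0`` and ``d = L + eps`` with the
    pulled-ensemble mean shift on eps.
    """
    rng = _rng_for(p.seed, F)
    kT = kbt(p.T)
    S_F = p.S + p.dSdF * F
    K = np.array([[S_F, p.g], [p.g, p.C]])
    Sigma = kT * p.L0 * np.linalg.inv(K)
    shift = rod_mean_shift(p, F)
    x = _ar1(rng, p.n_frames, 2, p.phi, np.linalg.cholesky(Sigma))
    L = p.L0 + shift[0] + x[:, 0]
    theta = p.theta0 + shift[1] + x[:, 1]
    if np.any(L <= 0):
        raise ValueError("generated non-positive extension; check parameters")
    ns = p.n_steps
    rise = np.repeat(L[:, None] / ns, ns, axis=1)
    twist = np.repeat(np.rad2deg(theta)[:, None] / ns, ns, axis=1)
    u = rise / p.cosbeta0
    eps = _ar1(rng, p.n_frames, 1, p.phi,
               np.array([[p.d_noise_sd]]))[:, 0]
    d = L + eps + F * p.d_noise_sd ** 2 / kT

    triads = None
    n_bp = ns + 1
    if p.lp_tau is not None and p.lp_rho is not None:
        Lbar = p.L0 / p.cosbeta0
        tau, rho, t2 = gen_bend_series(p.lp_tau, p.lp_rho, Lbar, p.n_frames,
                                       rng=rng)
        triads = np.full((p.n_frames, n_bp, 3, 3), np.nan)
        triads[:, 0] = t2[:, 0]
        triads[:, -1] = t2[:, 1]

    # a synthetic window sequence of the right length; the rod carries no
    # sequence information
    seq = ("GCAT" * (n_bp // 4 + 1))[:n_bp]
    return HelicalTrajectory(
        sequence=seq, force=F, temperature=p.T, rise=rise, twist=twist, u=u,
        anchor_distance=d, triads=triads,
        save_stride_note="synthetic harmonic rod",
    )


@dataclass
class MicroParams:
    """Ground truth for the per-step microstructure generator."""

    sequence: str = poly_xy_window_sequence("AC")
    k: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STEP_K))
    u0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STEP_U0))
    c0: float = 0.92
    k_beta: float = 2400.0     # pN
    cosbeta_sd: float | None = None   # default: equipartition-consistent
    twist_mean: float = 34.3   # deg
    twist_sd: float = 3.5      # deg
    slide0: float = -0.01      # nm, zero-force slide
    slide_slope: float = 2e-4  # nm/pN, force-induced slide change
    slide_sd: float = 0.05     # nm
    T: float = 300.0
    phi: float = 0.8
    d_noise_sd: float = 0.1
    n_frames: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.c0 <= 1.0):
            raise ValueError("c0 must be in (0, 1]")
        if self.k_beta <= 0:
            raise ValueError("k_beta must be positive")
        for s in self.step_types():
            if self.k[s] <= 0 or self.u0[s] <= 0:
                raise ValueError(f"step {s}: k and u0 must be positive")
        if self.cosbeta_sd is None:
            # equipartition of the crookedness channel: Var(cos b) such that
            # Var(L_beta) = kBT * L0 / k_beta with L0 = c0 * Lu
            Lu = sum(self.u0[s] for s in self.step_types())
            self.cosbeta_sd = math.sqrt(
                kbt(self.T) * self.c0 ** 2 / (self.k_beta * self.c0 * Lu))

    def step_types(self) -> list[str]:
        return [canonical_step(self.sequence[i:i + 2])
                for i in range(len(self.sequence) - 1)]

    def predicted_S_eff(self) -> float:
        """The series-of-springs S_eff implied by the ground truth."""
        steps = self.step_types()
        Lu = sum(self.u0[s] for s in steps)
        comp = sum(self.u0[s] / self.k[s] for s in steps) / Lu
        return 1.0 / (1.0 / self.k_beta + comp)


def gen_micro_trajectory(p: MicroParams, F: float) -> HelicalTrajectory:
    """Sample the per-step microstructure ensemble at force F.

    Per-step u_i are AR(1) Gaussians with mean ``u0_i (1 + F/k_i)`` and
    variance ``kBT u0_i / k_i``; cos(beta) is an AR(1) Gaussian with mean
    ``c0 (1 + F/k_beta)`` truncated to (0, 1] by redrawing violators
    (monitored; a warning fires above a 1% rejection rate); rises follow as
    ``rise_i = cos(beta) * u_i`` so that L = cos(beta) * sum(u) exactly.
    """
    rng = _rng_for(p.seed, F)
    kT = kbt(p.T)
    steps = p.step_types()
    ns = len(steps)
    u0 = np.array([p.u0[s] for s in steps])
    kk = np.array([p.k[s] for s in steps])
    u_mean = u0 * (1.0 + F / kk)
    u_sd = np.sqrt(kT * u0 / kk)
    u = u_mean + _ar1(rng, p.n_frames, ns, p.phi, np.diag(u_sd))
    if np.any(u <= 0):
        raise ValueError("generated non-positive u; parameters unphysical")

    cb_mean = p.c0 * (1.0 + F / p.k_beta)
    cb = cb_mean + _ar1(rng, p.n_frames, 1, p.phi,
                        np.array([[p.cosbeta_sd]]))[:, 0]
    bad = (cb <= 0.0) | (cb > 1.0)
    rate = bad.mean()
    if rate > 0.01:
        warnings.warn(
            f"cos(beta) truncation rejected {100 * rate:.2f}% of draws "
            "(> 1%): mean too close to 1 for the chosen noise",
            UserWarning, stacklevel=2)
    tries = 0
    while np.any(bad):
        cb[bad] = cb_mean + p.cosbeta_sd * rng.standard_normal(bad.sum())
        bad = (cb <= 0.0) | (cb > 1.0)
        tries += 1
        if tries > 100:
            raise RuntimeError("cos(beta) truncation failed to converge")

    rise = cb[:, None] * u
    twist = p.twist_mean + _ar1(rng, p.n_frames, ns, p.phi,
                                np.eye(ns) * p.twist_sd)
    slide = (p.slide0 + p.slide_slope * F) + _ar1(rng, p.n_frames, ns, p.phi,
                                                  np.eye(ns) * p.slide_sd)
    L = rise.sum(axis=1)
    eps = _ar1(rng, p.n_frames, 1, p.phi, np.array([[p.d_noise_sd]]))[:, 0]
    d = L + eps + F * p.d_noise_sd ** 2 / kT
    return HelicalTrajectory(
        sequence=p.sequence, force=F, temperature=p.T, rise=rise, twist=twist,
        slide=slide, u=u, anchor_distance=d,
        save_stride_note="synthetic microstructure",
    )


def gen_bend_series(lp_tau: float, lp_rho: float, Lbar: float, n: int,
                    seed: int = 0, twist_sd: float = 0.05,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """I.i.d. bending angles with Var = Lbar/lp per mode, plus triads.

    Returns ``(tau, rho, triads)`` with ``triads[f, 0]`` the first and
    ``triads[f, 1]`` the last base-pair frame: the first frame is the
    identity and the last realises the rotation vector (tau, rho, omega)
    with a small random twist omega, so the mid-frame decomposition returns
    the drawn angles exactly.
    """
    if lp_tau <= 0 or lp_rho <= 0 or Lbar <= 0:
        raise ValueError("persistence lengths and Lbar must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    tau = rng.standard_normal(n) * math.sqrt(Lbar / lp_tau)
    rho = rng.standard_normal(n) * math.sqrt(Lbar / lp_rho)
    omega = rng.standard_normal(n) * twist_sd
    rotvec = np.column_stack([tau, rho, omega])
    triads = np.empty((n, 2, 3, 3))
    triads[:, 0] = np.eye(3)
    triads[:, 1] = Rotation.from_rotvec(rotvec).as_matrix()
    return tau, rho, triads
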