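"""Per-snapshot global observables over an analysis window.

The duplex is summarised per frame by its extension ``L`` (sum of helical
rises), torsion ``theta`` (sum of twists, radians), the contour length of
the base-pair center line ``usum = sum_i u_i``, and the crookedness angle
``beta`` defined through ``cos(beta) = L / usum`` — beta = 0 means the
base-pair centers are perfectly aligned with the helical axis.  Global
bending is summarised by the generalized tilt/roll angles between the
terminal base-pair frames of the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import kbt
from .trajio import AnalysisWindow, HelicalTrajectory, TrajectoryValidationError

__all__ = ["ObservableSeries", "compute_observables", "bend_components"]

_COSBETA_TOL = 1e-9
_TRIAD_ORTHO_TOL = 1e-6


@dataclass
class ObservableSeries:
    """Per-frame global observables for one force; angles in radians."""

    L: np.ndarray                   # nm
    theta: np.ndarray               # rad
    cosbeta: np.ndarray
    beta: np.ndarray                # rad
    usum: np.ndarray                # nm
    force: float                    # pN
    temperature: float              # K
    d: np.ndarray | None = None     # nm, anchor distance
    tau: np.ndarray | None = None   # rad, generalized tilt
    rho: np.ndarray | None = None   # rad, generalized roll

    @property
    def n_frames(self) -> int:
        return len(self.L)

    @property
    def kBT(self) -> float:
        return kbt(self.temperature)


def compute_observables(traj: HelicalTrajectory,
                        window: AnalysisWindow | None = None) -> ObservableSeries:
    """Sum per-step parameters over the window into global observables.

    ``L[f] = sum rise``, ``theta[f] = sum twist`` (converted to radians here,
    the only place degrees leave the package), ``usum[f] = sum u`` and
    ``cosbeta = L/usum``.  The anchor distance is copied through if present.
    """
    if window is None:
        window = AnalysisWindow.central(traj.n_bp, min(10, traj.n_bp))
    window.check(traj.n_bp)
    if traj.u is None:
        raise TrajectoryValidationError(
            "center-to-center distances u are required for crookedness; "
            "provide a u column or base-pair centers"
        )
    sl = window.step_slice
    L = traj.rise[:, sl].sum(axis=1)
    theta = np.deg2rad(traj.twist[:, sl].sum(axis=1))
    usum = traj.u[:, sl].sum(axis=1)
    cosbeta = L / usum
    if np.any(cosbeta > 1.0 + _COSBETA_TOL):
        raise TrajectoryValidationError(
            f"cos(beta) exceeds 1 (max {cosbeta.max():.9f}): the summed rise "
            "cannot exceed the summed center-to-center distance"
        )
    cosbeta = np.minimum(cosbeta, 1.0)
    return ObservableSeries(
        L=L, theta=theta, cosbeta=cosbeta, beta=np.arccos(cosbeta), usum=usum,
        force=traj.force, temperature=traj.temperature,
        d=None if traj.anchor_distance is None else traj.anchor_distance.copy(),
    )


def _check_orthonormal(T: np.ndarray, what: str) -> None:
    err = np.abs(np.einsum("fij,fik->fjk", T, T) - np.eye(3)).max()
    if err > _TRIAD_ORTHO_TOL:
        raise TrajectoryValidationError(
            f"{what} triads deviate from orthonormality by {err:.3g} (> {_TRIAD_ORTHO_TOL})"
        )


def rotation_bend_decomposition(T_first: np.ndarray, T_last: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Generalized tilt/roll between two stacks of base-pair triads.

    The relative rotation carrying the first frame onto the last is taken in
    rotation-vector (matrix-logarithm) form and its components are read off
    in the *mid-frame* — the geodesic midpoint of the two orientations.  The
    component along the mid-frame short axis (axis 1) is the generalized
    tilt (bending toward the backbone), the component along the groove axis
    (axis 2) the generalized roll (bending toward the grooves); the helical
    component (twist) is discarded.

    This operator is deliberately isolated here so an alternative
    decomposition convention can be swapped in without touching callers.
    """
    _check_orthonormal(T_first, "first")
    _check_orthonormal(T_last, "last")
    A = Rotation.from_matrix(T_first)
    B = Rotation.from_matrix(T_last)
    rel = A.inv() * B
    mid = A * Rotation.from_rotvec(0.5 * rel.as_rotvec())
    v_lab = (B * A.inv()).as_rotvec()          # relative rotation, lab frame
    M = mid.as_matrix()                        # columns = mid-frame axes
    tau = np.einsum("fi,fi->f", v_lab, M[:, :, 0])
    rho = np.einsum("fi,fi->f", v_lab, M[:, :, 1])
    return tau, rho


def bend_components(traj: HelicalTrajectory, window: AnalysisWindow | None = None
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-frame generalized tilt/roll of the window plus mean contour length.

    Uses the triads of the first and last base pair of the window; ``Lbar``
    is the time average of the center-line contour length ``sum_i u_i``.
    """
    if window is None:
        window = AnalysisWindow.central(traj.n_bp, min(10, traj.n_bp))
    window.check(traj.n_bp)
    if traj.triads is None:
        raise TrajectoryValidationError("bending analysis requires base-pair triads")
    T1 = traj.triads[:, window.first]
    T2 = traj.triads[:, window.last]
    if np.any(np.isnan(T1)) or np.any(np.isnan(T2)):
        raise TrajectoryValidationError(
            f"triads missing for window-terminal base pairs {window.first}/{window.last}"
        )
    if traj.u is None:
        raise TrajectoryValidationError("contour length requires u or centers")
    tau, rho = rotation_bend_decomposition(T1, T2)
    Lbar = float(traj.u[:, window.step_slice].sum(axis=1).mean())
    return tau, rho, Lbar
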