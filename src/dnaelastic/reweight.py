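"""Free-energy-perturbation reweighting of the pulling ensemble.

The simulations apply the constant force along the line joining the pulled
anchor points, so the variable conjugated to ``F`` is the euclidean anchor
distance ``d``, not the contour length ``L`` the elastic description uses.
Remapping from the simulated ensemble (energy ``E(F) - F(dd - dL)``) to the
contour-length ensemble ``E(F)`` assigns every snapshot the Boltzmann weight

    w_f  ∝  exp[ F (L_f - d_f) / k_B T ],

valid whenever the two ensembles overlap appreciably.  Additive constants in
``L`` or ``d`` cancel on normalization, so raw values can be used directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .observables import ObservableSeries

__all__ = ["WeightedEnsemble", "fep_weights", "weighted_moments",
           "weighted_mean", "weighted_cov", "OverlapWarning"]


class OverlapWarning(UserWarning):
    """Effective sample size suspiciously small: poor ensemble overlap."""


@dataclass
class WeightedEnsemble:
    """An observable series with per-snapshot FEP weights (mean 1)."""

    series: ObservableSeries
    weights: np.ndarray
    ess: float
    F: float

    @property
    def n_frames(self) -> int:
        return len(self.weights)


def fep_weights(series: ObservableSeries, F: float | None = None, *,
                assume_d_equals_L: bool = False) -> WeightedEnsemble:
    """Boltzmann weights remapping the anchor-distance ensemble to E(F).

    With ``F = 0`` all weights are 1.  When ``d`` is missing the call fails
    unless ``assume_d_equals_L`` is set, in which case unit weights are used
    (with a warning): appropriate only if the anchor distance tracks the
    contour length exactly.
    """
    if F is None:
        F = series.force
    n = series.n_frames
    if F == 0.0:
        return WeightedEnsemble(series, np.ones(n), float(n), F)
    if series.d is None:
        if not assume_d_equals_L:
            raise ValueError(
                "anchor distance d is required for FEP reweighting at F != 0; "
                "provide it (or base-pair centers of the pulled pairs), or pass "
                "assume_d_equals_L=True to use unit weights"
            )
        warnings.warn("no anchor distance: assuming d == L, unit FEP weights",
                      OverlapWarning, stacklevel=2)
        return WeightedEnsemble(series, np.ones(n), float(n), F)
    expo = F * (series.L - series.d) / series.kBT
    expo -= expo.max()                      # overflow guard; constant cancels
    w = np.exp(expo)
    if not np.all(np.isfinite(w)):
        raise FloatingPointError(
            "non-finite FEP weight; center L and d or check units"
        )
    w *= n / w.sum()                        # normalize to mean 1
    ess = w.sum() ** 2 / np.sum(w ** 2)
    if ess < 0.1 * n:
        warnings.warn(
            f"effective sample size {ess:.0f} < 10% of {n} frames: the "
            "simulated and target ensembles may not overlap enough for FEP",
            OverlapWarning, stacklevel=2)
    return WeightedEnsemble(series, w, float(ess), float(F))


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted central second moment, no small-sample correction."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    return float(np.sum(w * (x - mx) * (y - my)) / sw)


def weighted_moments(values: np.ndarray | list[np.ndarray],
                     ensemble: WeightedEnsemble
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted means and covariance matrix of one or more per-frame vectors.

    Returns ``(means, cov)`` with ``cov[i, j]`` the weighted central second
    moment between series i and j (so ``cov[i, i]`` is the variance).
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    w = ensemble.weights
    if vals.shape[1] != len(w):
        raise ValueError(
            f"values have {vals.shape[1]} frames, ensemble has {len(w)}"
        )
    sw = w.sum()
    means = vals @ w / sw
    centered = vals - means[:, None]
    cov = (centered * w) @ centered.T / sw
    return means, cov
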