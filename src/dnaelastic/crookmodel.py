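"""Crookedness-based prediction of the stretch modulus.

The stretching response of a duplex decomposes into two serial mechanisms:
aligning the base-pair centers with the helical axis (crookedness, stiffness
``k_beta``) and elongating the center-to-center distances of the individual
dinucleotide steps (stiffness ``k_i``, zero-force length ``u0_i``).  To first
order in the force this is a series of springs,

    1 / S_eff = 1 / k_beta + (1 / L_u) * sum_i u0_i / k_i,     L_u = sum_i u0_i,

obtained by expanding ``<L>_F = <cos b>_F * sum_i <u_i>_F``.  Across
sequences and force fields ``k_beta`` collapses onto a single empirical
curve in the unperturbed crookedness,

    k_beta(b0) = A * exp(-D * b0) + B,

so the effective modulus of a fragment is predictable from its sequence
(via the tabulated step constants) and its zero-force structure (via b0)
alone.  The share of the total compliance carried by crookedness is
``S_eff / k_beta``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .elasticity import StepSlopes
from .uncertainty import combine_fit_errors

__all__ = [
    "STEP_TYPES", "canonical_step", "CrookCurve", "StepTable",
    "fit_crook_curve", "eval_crook_curve", "fit_step_table",
    "merge_step_tables", "predict_stretch_modulus", "crook_contribution",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the ten distinct dinucleotide steps (reverse-complement symmetry), named
#: by the representatives occurring in the poly-XY repeat sequences
STEP_TYPES = ("AA", "AC", "AG", "AT", "CA", "CG", "GA", "GC", "GG", "TA")


def canonical_step(step: str) -> str:
    """Canonical name of a dinucleotide step (XY == revcomp(XY))."""
    step = step.upper()
    if step in STEP_TYPES:
        return step
    rc = step.translate(_COMPLEMENT)[::-1]
    if rc in STEP_TYPES:
        return rc
    raise ValueError(f"not a dinucleotide step: {step!r}")


@dataclass
class CrookCurve:
    """Parameters of the empirical law k_beta(b0) = A exp(-D b0) + B.

    ``b0`` is in radians; A and B in pN, D dimensionless.  ``beta_unit``
    records the angular unit the curve was calibrated against and is kept as
    an explicit knob ("rad" or "deg").
    """

    A: float
    B: float
    D: float
    dA: float = 0.0
    dB: float = 0.0
    dD: float = 0.0
    beta_unit: str = "rad"

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.D <= 0:
            raise ValueError("CrookCurve requires A, B, D > 0")
        if self.beta_unit not in ("rad", "deg"):
            raise ValueError("beta_unit must be 'rad' or 'deg'")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame([{"A_pN": self.A, "dA_pN": self.dA, "B_pN": self.B,
                       "dB_pN": self.dB, "D": self.D, "dD": self.dD,
                       "beta_unit": self.beta_unit}]).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrookCurve":
        r = pd.read_csv(path).iloc[0]
        return cls(A=r["A_pN"], B=r["B_pN"], D=r["D"], dA=r["dA_pN"],
                   dB=r["dB_pN"], dD=r["dD"], beta_unit=str(r["beta_unit"]))


@dataclass
class StepTable:
    """Per-dinucleotide-step elastic constant k (pN) and zero-force
    center-to-center distance u0 (nm), with errors and provenance."""

    k: dict[str, float]
    u0: dict[str, float]
    dk: dict[str, float] = field(default_factory=dict)
    du0: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, v in self.k.items():
            if v <= 0:
                raise ValueError(f"step {s}: k must be positive, got {v}")
        for s, v in self.u0.items():
            if not (0.2 < v < 0.6):
                raise ValueError(
                    f"step {s}: u0 = {v} nm outside the physical band (0.2, 0.6)"
                )

    @property
    def steps(self) -> set[str]:
        return set(self.k)

    def require_complete(self) -> None:
        missing = sorted(set(STEP_TYPES) - self.steps)
        if missing:
            raise ValueError(f"step table incomplete; missing steps: {missing}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [{"step": s, "k_pN": self.k[s], "dk_pN": self.dk.get(s, 0.0),
                 "u0_nm": self.u0[s], "du0_nm": self.du0.get(s, 0.0)}
                for s in sorted(self.k)]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "StepTable":
        df = pd.read_csv(path)
        return cls(
            k={r.step: r.k_pN for r in df.itertuples()},
            u0={r.step: r.u0_nm for r in df.itertuples()},
            dk={r.step: r.dk_pN for r in df.itertuples()},
            du0={r.step: r.du0_nm for r in df.itertuples()},
        )


def _curve(b0, A, B, D):
    # clipping keeps wild multistart excursions finite for the optimizer
    with np.errstate(over="ignore"):
        y = A * np.exp(-np.clip(D * b0, -700.0, 700.0)) + B
    return np.nan_to_num(y, posinf=1e300, neginf=-1e300)


def fit_crook_curve(points: list[tuple[float, float, float]],
                    n_mc: int = 1000, seed: int = 0) -> CrookCurve:
    """Nonlinear least squares of k_beta(b0) = A exp(-D b0) + B.

    ``points`` are (b0 [rad], k_beta [pN], dk [pN]) triples.  Multistart
    initialisation over a decade of decay rates; the error has a
    least-squares channel (parameter covariance) and a Monte-Carlo channel
    (points perturbed by dk, refit), combined in quadrature.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 (beta0, k_beta, dk) points")
    b0, k, dk = pts.T
    if np.ptp(b0) <= 0:
        raise ValueError("beta0 values must span a range")

    def _fit(kvals):
        best = None
        B_start = max(min(kvals) * 0.8, 1.0)
        A_start = max(max(kvals) - B_start, 1.0)
        for D_start in (1.0, 5.0, 10.0, 20.0, 40.0):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # multistart diagnostics
                    popt, pcov = curve_fit(
                        _curve, b0, kvals, p0=(A_start, B_start, D_start),
                        maxfev=20000, xtol=1e-14, ftol=1e-14)
            except RuntimeError:
                continue
            rss = float(np.sum((_curve(b0, *popt) - kvals) ** 2))
            if np.all(popt > 0) and (best is None or rss < best[0]):
                best = (rss, popt, pcov)
        if best is None:
            raise RuntimeError(
                "crookedness-curve fit failed to converge from all starts; "
                f"beta0 range [{b0.min():.3g}, {b0.max():.3g}], "
                f"k range [{kvals.min():.3g}, {kvals.max():.3g}]"
            )
        return best

    _, popt, pcov = _fit(k)
    A, B, D = popt
    if A < 1e-6 * B:
        warnings.warn("fitted A ~ 0: no crookedness decay in the data "
                      "(flat k_beta); curve is degenerate", UserWarning,
                      stacklevel=2)
    d_ave = np.sqrt(np.clip(np.diag(pcov), 0, None))
    d_ind = np.zeros(3)
    if np.any(dk > 0):
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_mc):
            ks = k + rng.standard_normal(len(k)) * dk
            try:
                _, p, _ = _fit(ks)
                samples.append(p)
            except RuntimeError:
                continue
        if samples:
            d_ind = np.std(np.array(samples), axis=0)
    dA, dB, dD = (combine_fit_errors(a, i) for a, i in zip(d_ave, d_ind))
    return CrookCurve(A=float(A), B=float(B), D=float(D),
                      dA=float(dA), dB=float(dB), dD=float(dD))


def eval_crook_curve(curve: CrookCurve, beta0: float) -> tuple[float, float]:
    """k_beta at a given unperturbed crookedness, with propagated error."""
    b = beta0 if curve.beta_unit == "rad" else math.degrees(beta0)
    e = math.exp(-curve.D * b)
    k = curve.A * e + curve.B
    dk = math.sqrt((e * curve.dA) ** 2 + curve.dB ** 2 +
                   (curve.A * b * e * curve.dD) ** 2)
    return float(k), float(dk)


def fit_step_table(results: list[tuple[str, StepSlopes]]) -> StepTable:
    """Aggregate per-step (k, u0) fits from several sequences into one table.

    ``results`` pairs each window sequence string (n_bp characters) with the
    ``StepSlopes`` of its ``u`` parameter.  Values for each of the ten step
    types are unweighted means over all occurrences; the error combines the
    spread across occurrences with the propagated individual errors in
    quadrature.
    """
    occ: dict[str, list[tuple[float, float, float, float, str]]] = {}
    for seq, slopes in results:
        if slopes.k is None:
            raise ValueError("StepSlopes must come from the 'u' parameter")
        if len(seq) != len(slopes.step_index) + 1:
            raise ValueError(
                f"sequence length {len(seq)} does not match "
                f"{len(slopes.step_index)} steps"
            )
        for j, si in enumerate(slopes.step_index):
            step = canonical_step(seq[j:j + 2])
            occ.setdefault(step, []).append(
                (slopes.k[j], slopes.dk[j], slopes.u0[j], slopes.du0[j],
                 f"{seq}:{si}")
            )
    k, u0, dk, du0, prov = {}, {}, {}, {}, {}
    for step, entries in occ.items():
        ks = np.array([e[0] for e in entries])
        dks = np.array([e[1] for e in entries])
        u0s = np.array([e[2] for e in entries])
        du0s = np.array([e[3] for e in entries])
        m = len(entries)
        k[step] = float(ks.mean())
        u0[step] = float(u0s.mean())
        dk[step] = float(np.sqrt(ks.var() / m + np.sum(dks ** 2) / m ** 2))
        du0[step] = float(np.sqrt(u0s.var() / m + np.sum(du0s ** 2) / m ** 2))
        prov[step] = [e[4] for e in entries]
    return StepTable(k=k, u0=u0, dk=dk, du0=du0, provenance=prov)


def merge_step_tables(tables: list[StepTable]) -> StepTable:
    """Unweighted mean of several step tables (e.g. one per force field)."""
    steps = set.intersection(*(t.steps for t in tables))
    k, u0, dk, du0 = {}, {}, {}, {}
    for s in steps:
        ks = np.array([t.k[s] for t in tables])
        us = np.array([t.u0[s] for t in tables])
        m = len(tables)
        k[s] = float(ks.mean())
        u0[s] = float(us.mean())
        dk[s] = float(np.sqrt(np.sum([t.dk.get(s, 0.0) ** 2 for t in tables]) / m ** 2))
        du0[s] = float(np.sqrt(np.sum([t.du0.get(s, 0.0) ** 2 for t in tables]) / m ** 2))
    return StepTable(k=k, u0=u0, dk=dk, du0=du0)


def predict_stretch_modulus(sequence: str, beta0: float, curve: CrookCurve,
                            table: StepTable, dbeta0: float = 0.0
                            ) -> tuple[float, float]:
    """Series-of-springs prediction of S_eff from sequence and crookedness.

    ``sequence`` is the analysis-window sequence (its steps must all be in
    the table); ``beta0`` the unperturbed crookedness in radians.  Error by
    first-order propagation through k_beta (curve evaluation, including
    dbeta0), the step constants and the zero-force lengths.
    """
    steps = [canonical_step(sequence[i:i + 2]) for i in range(len(sequence) - 1)]
    missing = sorted(set(steps) - table.steps)
    if missing:
        raise ValueError(f"steps missing from table: {missing}")
    k_beta, dk_beta = eval_crook_curve(curve, beta0)
    if dbeta0:
        b = beta0 if curve.beta_unit == "rad" else math.degrees(beta0)
        db = dbeta0 if curve.beta_unit == "rad" else math.degrees(dbeta0)
        dk_beta = math.hypot(dk_beta, curve.A * curve.D * math.exp(-curve.D * b) * db)
    if k_beta <= 0:
        raise ValueError(f"k_beta = {k_beta} <= 0")
    u0 = np.array([table.u0[s] for s in steps])
    kk = np.array([table.k[s] for s in steps])
    du0 = np.array([table.du0.get(s, 0.0) for s in steps])
    dkk = np.array([table.dk.get(s, 0.0) for s in steps])
    if np.any(kk <= 0):
        raise ValueError("all step constants k_i must be positive")
    Lu = u0.sum()
    comp_steps = float(np.sum(u0 / kk)) / Lu
    inv_S = 1.0 / k_beta + comp_steps
    S_eff = 1.0 / inv_S
    # first-order error on 1/S_eff
    var = (dk_beta / k_beta ** 2) ** 2
    var += np.sum((u0 * dkk / (kk ** 2 * Lu)) ** 2)
    var += np.sum(((1.0 / (kk * Lu) - comp_steps / Lu) * du0) ** 2)
    dS_eff = S_eff ** 2 * math.sqrt(var)
    return float(S_eff), float(dS_eff)


def crook_contribution(S_eff: float, k_beta: float) -> float:
    """Fraction of the stretch compliance carried by crookedness:
    (1/k_beta) / (1/S_eff) = S_eff / k_beta, clipped to [0, 1]."""
    if S_eff <= 0 or k_beta <= 0:
        raise ValueError("S_eff and k_beta must be positive")
    frac = S_eff / k_beta
    if frac > 1.0:
        warnings.warn(
            f"S_eff ({S_eff:.4g} pN) exceeds k_beta ({k_beta:.4g} pN); "
            "contribution clipped to 1", UserWarning, stacklevel=2)
        frac = 1.0
    return float(frac)
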