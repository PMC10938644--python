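"""Orchestration of the full per-sequence elastic study.

For one sequence simulated at several constant forces (F = 0 required, the
standard set being 0, 1, 5, 10, 15, 20 pN) the study runs, per force:
window observables, FEP reweighting, weighted means and covariances with
block-bootstrap errors; then the slope-based effective stretch modulus and
crookedness stiffness, the fluctuation-based S, C, g, S_eff per force with
their linear force trends, zero-force bending persistence lengths, and —
when a crookedness curve and step table are supplied — the series-of-springs
prediction of S_eff and the crookedness contribution.

The in-memory entry point is :func:`analyze_force_series`;
:func:`run_force_series` wraps it with config-file handling, trajectory
loading and report writing (JSON + human-readable text + run log).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .bending import PersistenceResult, per_step_bend_variance, persistence_lengths
from .crookmodel import CrookCurve, StepTable, crook_contribution, predict_stretch_modulus
from .elasticity import (ElasticConstants, constants_from_fluctuations,
                         crookedness_stiffness, fit_force_response,
                         force_dependence, stretch_modulus_effective)
from .observables import bend_components, compute_observables
from .reweight import fep_weights, weighted_mean
from .trajio import AnalysisWindow, HelicalTrajectory, read_trajectory
from .uncertainty import block_bootstrap_error

__all__ = ["StudyReport", "analyze_force_series", "run_force_series",
           "run_zero_force", "load_config"]

log = logging.getLogger(__name__)


def _ve(value: float, error: float) -> dict[str, float]:
    return {"value": float(value), "error": float(error)}


@dataclass
class StudyReport:
    """Machine-readable results of one per-sequence study."""

    sequence: str
    window: tuple[int, int]
    seed: int
    forces: list[float]
    L0: dict[str, float]
    theta0: dict[str, float]
    beta0: dict[str, float]
    c0: dict[str, float] | None = None
    k_beta: dict[str, float] | None = None
    S_eff_slope: dict[str, float] | None = None
    per_force: list[dict[str, Any]] = field(default_factory=list)
    dS_dF: dict[str, float] | None = None
    dC_dF: dict[str, float] | None = None
    dg_dF: dict[str, float] | None = None
    persistence: dict[str, Any] | None = None
    crook_prediction: dict[str, Any] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "package_version": __version__,
            "sequence": self.sequence,
            "window": list(self.window),
            "seed": self.seed,
            "forces_pN": self.forces,
            "L0_nm": self.L0,
            "theta0_rad": self.theta0,
            "beta0_rad": self.beta0,
            "c0": self.c0,
            "k_beta_pN": self.k_beta,
            "S_eff_slope_pN": self.S_eff_slope,
            "per_force": self.per_force,
            "dS_dF": self.dS_dF,
            "dC_dF": self.dC_dF,
            "dg_dF": self.dg_dF,
            "persistence": self.persistence,
            "crook_prediction": self.crook_prediction,
            "notes": self.notes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [f"dnaelastic study report (v{__version__})",
                 f"sequence {self.sequence}  window {self.window}  seed {self.seed}",
                 f"forces (pN): {self.forces}", ""]

        def fmt(name, rec, unit=""):
            if rec is None:
                return f"{name:<18s} unavailable"
            return f"{name:<18s} {rec['value']:#.6g} +/- {rec['error']:#.3g} {unit}"

        lines.append(fmt("L0", d["L0_nm"], "nm"))
        lines.append(fmt("theta0", d["theta0_rad"], "rad"))
        lines.append(fmt("beta0", d["beta0_rad"], "rad"))
        lines.append(fmt("S_eff (slope)", d["S_eff_slope_pN"], "pN"))
        lines.append(fmt("c0", d["c0"]))
        lines.append(fmt("k_beta", d["k_beta_pN"], "pN"))
        lines.append("")
        for rec in self.per_force:
            lines.append(f"F = {rec['F_pN']} pN  (ESS {rec['ess']:.0f})")
            for key, unit in (("S_pN", "pN"), ("C_pNnm2", "pN nm^2"),
                              ("g_pNnm", "pN nm"), ("S_eff_pN", "pN")):
                if rec.get(key) is not None:
                    lines.append("  " + fmt(key, rec[key], unit))
        lines.append("")
        for name, key in (("dS/dF", "dS_dF"), ("dC/dF", "dC_dF"), ("dg/dF", "dg_dF")):
            lines.append(fmt(name, d[key]))
        if self.persistence:
            lines.append("")
            for key, unit in (("lp_tau_nm", "nm"), ("lp_rho_nm", "nm"),
                              ("lp_nm", "nm")):
                lines.append(fmt(key, self.persistence[key], unit))
        if self.crook_prediction:
            lines.append("")
            lines.append(fmt("S_eff predicted", self.crook_prediction["S_eff_pred_pN"], "pN"))
            lines.append(f"{'crook share':<18s} {self.crook_prediction['contribution']:.3f}")
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines) + "\n"


def analyze_force_series(trajs: list[HelicalTrajectory],
                         window: AnalysisWindow | None = None,
                         seed: int = 0, n_boot: int = 1000,
                         max_sizes: int = 400, n_mc: int = 1000,
                         curve: CrookCurve | None = None,
                         table: StepTable | None = None,
                         errors: str = "block") -> StudyReport:
    """Run the full study on in-memory trajectories (one per force).

    Requires an F = 0 trajectory; with fewer than three forces the
    slope-based quantities are reported as unavailable rather than failing.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    seqs = {t.sequence for t in trajs}
    if len(seqs) > 1:
        raise ValueError(f"inconsistent sequences across forces: {sorted(seqs)}")
    forces = [t.force for t in trajs]
    if len(set(forces)) != len(forces):
        raise ValueError("duplicate forces in the input set")
    if 0.0 not in forces:
        raise ValueError("an F = 0 trajectory is required")
    trajs = sorted(trajs, key=lambda t: t.force)
    n_bp = trajs[0].n_bp
    if window is None:
        window = AnalysisWindow.central(n_bp, 10) if n_bp >= 14 \
            else AnalysisWindow(0, n_bp - 1)

    report = StudyReport(sequence=trajs[0].sequence[window.bp_slice],
                         window=(window.first, window.last), seed=seed,
                         forces=[t.force for t in trajs],
                         L0={}, theta0={}, beta0={})

    series = [compute_observables(t, window) for t in trajs]
    ensembles = [fep_weights(s) for s in series]
    ens0 = next(e for e in ensembles if e.F == 0.0)

    def mean_err(vals, ens, sd):
        m = weighted_mean(vals, ens.weights)
        if errors == "block":
            e = block_bootstrap_error(vals, ens, "mean", n_boot=n_boot,
                                      seed=sd, max_sizes=max_sizes).final_error
        else:
            w = ens.weights
            var = np.sum(w * (vals - m) ** 2) / np.sum(w)
            e = math.sqrt(var / ens.ess)
        return m, e

    L0, dL0 = mean_err(ens0.series.L, ens0, seed + 11)
    th0, dth0 = mean_err(ens0.series.theta, ens0, seed + 12)
    b0, db0 = mean_err(ens0.series.beta, ens0, seed + 13)
    report.L0 = _ve(L0, dL0)
    report.theta0 = _ve(th0, dth0)
    report.beta0 = _ve(b0, db0)

    # per-force averages and fluctuation constants
    pts_dL, pts_cb = [], []
    constants: list[ElasticConstants] = []
    for i, ens in enumerate(ensembles):
        mL, eL = mean_err(ens.series.L, ens, seed + 100 + 7 * i)
        mcb, ecb = mean_err(ens.series.cosbeta, ens, seed + 101 + 7 * i)
        pts_dL.append((ens.F, mL - L0, eL))
        pts_cb.append((ens.F, mcb, ecb))
        rec: dict[str, Any] = {"F_pN": ens.F, "ess": ens.ess,
                               "mean_L_nm": _ve(mL, eL),
                               "mean_cosbeta": _ve(mcb, ecb)}
        try:
            ec = constants_from_fluctuations(
                ens, L0, errors=errors, n_boot=n_boot,
                seed=seed + 200 + 11 * i, max_sizes=max_sizes)
            constants.append(ec)
            rec.update(S_pN=_ve(ec.S, ec.dS), C_pNnm2=_ve(ec.C, ec.dC),
                       g_pNnm=_ve(ec.g, ec.dg), S_eff_pN=_ve(ec.S_eff, ec.dS_eff),
                       positive_definite=ec.positive_definite)
        except ValueError as exc:
            rec["fluctuation_error"] = str(exc)
            report.notes.append(f"F={ens.F}: fluctuation constants failed: {exc}")
        report.per_force.append(rec)

    if len(trajs) >= 3:
        fit_dL = fit_force_response(pts_dL, n_mc=n_mc, seed=seed + 1)
        S_eff, dS_eff = stretch_modulus_effective(fit_dL, L0, dL0)
        report.S_eff_slope = _ve(S_eff, dS_eff)
        fit_cb = fit_force_response(pts_cb, n_mc=n_mc, seed=seed + 2)
        c0, k_beta, dc0, dk_beta = crookedness_stiffness(fit_cb)
        report.c0 = _ve(c0, dc0)
        report.k_beta = _ve(k_beta, dk_beta)
        if len(constants) >= 3:
            for off, (name, attr) in enumerate(
                    (("dS_dF", "S"), ("dC_dF", "C"), ("dg_dF", "g"))):
                f = force_dependence(constants, attr, n_mc=n_mc,
                                     seed=seed + 3 + off)
                setattr(report, name, _ve(f.slope, f.delta_slope))
    else:
        report.notes.append(
            "fewer than 3 forces: slope-based quantities unavailable")

    traj0 = next(t for t in trajs if t.force == 0.0)
    if traj0.triads is not None:
        try:
            tau, rho, Lbar = bend_components(traj0, window)
            pr: PersistenceResult = persistence_lengths(
                tau, rho, Lbar, errors=errors, n_boot=n_boot,
                seed=seed + 31, max_sizes=max_sizes)
            report.persistence = {
                "lp_tau_nm": _ve(pr.lp_tau, pr.dlp_tau),
                "lp_rho_nm": _ve(pr.lp_rho, pr.dlp_rho),
                "lp_nm": _ve(pr.lp, pr.dlp),
                "Lbar_nm": pr.Lbar,
            }
        except Exception as exc:
            report.notes.append(f"bending analysis failed: {exc}")
    if traj0.tilt is not None and traj0.roll is not None:
        vt, vr, flag = per_step_bend_variance(traj0, window)
        report.notes.append(
            f"per-step roll variance exceeds tilt variance on "
            f"{int(flag.sum())}/{len(flag)} steps")

    if curve is not None and table is not None:
        try:
            S_pred, dS_pred = predict_stretch_modulus(
                report.sequence, b0, curve, table, dbeta0=db0)
            kb_from_curve = None
            if report.k_beta is not None and math.isfinite(report.k_beta["value"]):
                share = crook_contribution(S_pred, report.k_beta["value"])
            else:
                from .crookmodel import eval_crook_curve
                kb_from_curve, _ = eval_crook_curve(curve, b0)
                share = crook_contribution(S_pred, kb_from_curve)
            report.crook_prediction = {
                "S_eff_pred_pN": _ve(S_pred, dS_pred),
                "contribution": share,
            }
        except ValueError as exc:
            report.notes.append(f"crookedness prediction failed: {exc}")
    return report


# ---------------------------------------------------------------------------
# config-file driver

_DEFAULTS = dict(seed=0, n_boot=1000, max_block_sizes=400, n_mc=1000,
                 errors="block")


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "trajectories" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with a "
                         "'trajectories' section (force -> file)")
    return cfg


def _parse_window(spec, n_bp: int) -> AnalysisWindow | None:
    if spec in (None, "central10"):
        return None
    if spec == "full":
        return AnalysisWindow(0, n_bp - 1)
    if isinstance(spec, str) and ":" in spec:
        first, last = spec.split(":")
        return AnalysisWindow(int(first), int(last))
    first, last = spec
    return AnalysisWindow(int(first), int(last))


def run_force_series(config: dict[str, Any] | str | Path,
                     out_dir: str | Path | None = None) -> StudyReport:
    """Config-driven study: load trajectories, analyze, write reports."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**_DEFAULTS, **config}
    trajs = [read_trajectory(p, cfg.get("format", "canonical"))
             for p in cfg["trajectories"].values()]
    declared = [float(F) for F in cfg["trajectories"]]
    actual = [t.force for t in trajs]
    if sorted(declared) != sorted(actual):
        raise ValueError(
            f"config forces {sorted(declared)} disagree with file headers "
            f"{sorted(actual)}")
    curve = CrookCurve.from_csv(cfg["curve"]) if cfg.get("curve") else None
    table = StepTable.from_csv(cfg["step_table"]) if cfg.get("step_table") else None
    window = _parse_window(cfg.get("window"), trajs[0].n_bp)
    report = analyze_force_series(
        trajs, window=window, seed=int(cfg["seed"]), n_boot=int(cfg["n_boot"]),
        max_sizes=int(cfg["max_block_sizes"]), n_mc=int(cfg["n_mc"]),
        curve=curve, table=table, errors=cfg["errors"])
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    echo = {k: v for k, v in cfg.items()}
    echo["trajectories"] = {str(k): str(v) for k, v in cfg["trajectories"].items()}
    (out / "run_log.json").write_text(json.dumps(
        {"package_version": __version__, "config": echo}, indent=2,
        sort_keys=True, default=str))
    log.info("report written to %s", out)
    return report


def run_zero_force(config: dict[str, Any] | str | Path,
                   out_dir: str | Path | None = None) -> StudyReport:
    """Zero-force study: covariance-based constants and bending only."""
    if not isinstance(config, dict):
        config = load_config(config)
    forces = [float(F) for F in config["trajectories"]]
    if forces != [0.0]:
        raise ValueError("zero-force mode takes exactly one F = 0 trajectory")
    return run_force_series(config, out_dir=out_dir)
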