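#!/usr/bin/env python
"""Persistence lengths of every study sequence from terminal-frame bending.

Fragment-level generalized tilt/roll fluctuations give the per-mode
persistence lengths and their harmonic mean; per-step tilt/roll variances
illustrate the inversion of the anisotropy at the local scale (roll softer
than tilt per step, stiffer than tilt globally).  Writes
results/persistence.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dnaelastic import (AnalysisWindow, bend_components,
                        per_step_bend_variance, persistence_lengths)
from dnaelastic.studyset import BEND_TRUTH, STUDY_SEQUENCES, generate_study

SEED = 11
N_FRAMES = 20_000
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name in sorted(STUDY_SEQUENCES):
        t0 = generate_study(name, n_frames=N_FRAMES, seed=SEED,
                            forces=(0.0,))[0]
        window = AnalysisWindow(0, t0.n_bp - 1)
        tau, rho, Lbar = bend_components(t0, window)
        r = persistence_lengths(tau, rho, Lbar, errors="block", n_boot=200,
                                seed=SEED, max_sizes=100)
        vt, vr, flag = per_step_bend_variance(t0, window)
        rows.append({
            "sequence": name, "Lbar_nm": Lbar,
            "lp_tau_nm": r.lp_tau, "dlp_tau_nm": r.dlp_tau,
            "lp_rho_nm": r.lp_rho, "dlp_rho_nm": r.dlp_rho,
            "lp_nm": r.lp, "dlp_nm": r.dlp,
            "lp_tau_truth_nm": BEND_TRUTH[name][0],
            "lp_rho_truth_nm": BEND_TRUTH[name][1],
            "steps_with_roll_softer": int(flag.sum()),
            "n_steps": len(flag),
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "persistence.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print("\nglobal anisotropy: lp_rho > lp_tau for every sequence "
          f"({(df.lp_rho_nm > df.lp_tau_nm).all()}); locally the ordering "
          "inverts, with per-step roll variance above tilt variance on "
          f"{df.steps_with_roll_softer.sum()}/{df.n_steps.sum()} steps.")


if __name__ == "__main__":
    main()
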