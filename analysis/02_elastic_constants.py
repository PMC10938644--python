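#!/usr/bin/env python
"""Per-sequence elastic constants across the force range.

For every sequence of the synthetic study set: the effective stretch
modulus from the force-extension slope, the fluctuation-based S, C, g and
S_eff = S - g^2/C at each force, and the linear force trends dS/dF, dC/dF,
dg/dF.  Writes results/elastic_constants.csv (per force) and
results/force_trends.csv (per sequence).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dnaelastic import analyze_force_series
from dnaelastic.studyset import STUDY_SEQUENCES, generate_study, study_params

SEED = 11
N_FRAMES = 20_000
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    per_force, trends = [], []
    for name in sorted(STUDY_SEQUENCES):
        trajs = generate_study(name, n_frames=N_FRAMES, seed=SEED,
                               with_bending=False)
        rep = analyze_force_series(trajs, seed=SEED, n_boot=200, max_sizes=100,
                                   n_mc=300)
        p = study_params(name, N_FRAMES, SEED)
        for rec in rep.per_force:
            if "S_pN" not in rec:
                continue
            per_force.append({
                "sequence": name, "F_pN": rec["F_pN"],
                "S_pN": rec["S_pN"]["value"], "dS_pN": rec["S_pN"]["error"],
                "C_pNnm2": rec["C_pNnm2"]["value"],
                "dC_pNnm2": rec["C_pNnm2"]["error"],
                "g_pNnm": rec["g_pNnm"]["value"],
                "dg_pNnm": rec["g_pNnm"]["error"],
                "S_eff_pN": rec["S_eff_pN"]["value"],
            })
        trends.append({
            "sequence": name,
            "S_eff_slope_pN": rep.S_eff_slope["value"],
            "dS_eff_slope_pN": rep.S_eff_slope["error"],
            "S_eff_truth_pN": p.predicted_S_eff(),
            "dS_dF": rep.dS_dF["value"], "ddS_dF": rep.dS_dF["error"],
            "dC_dF": rep.dC_dF["value"], "dg_dF": rep.dg_dF["value"],
        })
    pd.DataFrame(per_force).to_csv(RESULTS / "elastic_constants.csv", index=False)
    tdf = pd.DataFrame(trends)
    tdf.to_csv(RESULTS / "force_trends.csv", index=False)
    print(tdf.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    ok = ((tdf.S_eff_slope_pN - tdf.S_eff_truth_pN).abs()
          < 3 * tdf.dS_eff_slope_pN + 0.05 * tdf.S_eff_truth_pN).all()
    print(f"\nslope-route S_eff matches the generating truth for all "
          f"sequences: {bool(ok)}; force trends are flat (no stiffening "
          "built into this study set).")


if __name__ == "__main__":
    main()
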