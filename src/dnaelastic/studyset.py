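"""The default synthetic study set: seven sequences, six forces.

Mirrors the design of the MD study the analysis was built for: six poly-XY
repeats (pentamers of AA, AC, AG, AT, CG, GG, jointly covering the ten
distinct dinucleotide steps) plus a random-like 16-mer containing all ten
steps.  Each sequence gets its own unperturbed crookedness; its crookedness
stiffness follows self-consistently from the published-scale exponential
law, so the cross-sequence curve fit and the series-of-springs prediction
have a well-defined ground truth.  Bending ground truth makes the roll
persistence length exceed the tilt one at the fragment level, while
per-step roll fluctuations exceed tilt fluctuations locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crookmodel import CrookCurve, eval_crook_curve
from .synthgen import (MicroParams, RNG_SEQUENCE, gen_bend_series,
                       gen_micro_trajectory, poly_xy_window_sequence)
from .trajio import HelicalTrajectory

__all__ = ["STUDY_SEQUENCES", "REFERENCE_CURVE", "study_params",
           "generate_study", "FORCES"]

FORCES = (0.0, 1.0, 5.0, 10.0, 15.0, 20.0)

#: unperturbed crookedness assigned to each sequence (poly-AA straightest,
#: poly-GG most crooked)
STUDY_SEQUENCES = {
    "RNG": 0.92,
    "poly-AA": 0.96,
    "poly-AC": 0.93,
    "poly-AG": 0.94,
    "poly-AT": 0.91,
    "poly-CG": 0.90,
    "poly-GG": 0.88,
}

#: published-scale crookedness-stiffness law used as generating truth
REFERENCE_CURVE = CrookCurve(A=2.9e5, B=736.0, D=12.8)

#: fragment-level bending ground truth (nm); roll softer than tilt is never
#: the case here: lp_rho > lp_tau throughout, as for fragments of this size
BEND_TRUTH = {
    "RNG": (48.0, 62.0), "poly-AA": (60.0, 80.0), "poly-AC": (45.0, 58.0),
    "poly-AG": (55.0, 72.0), "poly-AT": (42.0, 55.0), "poly-CG": (50.0, 66.0),
    "poly-GG": (70.0, 95.0),
}


def study_params(name: str, n_frames: int = 20_000, seed: int = 0) -> MicroParams:
    """Generating parameters for one sequence of the study set."""
    if name not in STUDY_SEQUENCES:
        raise KeyError(f"unknown study sequence {name!r}")
    seq = RNG_SEQUENCE if name == "RNG" else poly_xy_window_sequence(name[-2:])
    c0 = STUDY_SEQUENCES[name]
    beta0 = math.acos(c0)
    k_beta, _ = eval_crook_curve(REFERENCE_CURVE, beta0)
    idx = sorted(STUDY_SEQUENCES).index(name)
    return MicroParams(sequence=seq, c0=c0, k_beta=k_beta,
                       n_frames=n_frames, seed=seed * 131 + idx)


def generate_study(name: str, n_frames: int = 20_000, seed: int = 0,
                   forces=FORCES, with_bending: bool = True
                   ) -> list[HelicalTrajectory]:
    """One trajectory per force for a study sequence.

    The F = 0 trajectory additionally carries terminal triads realising the
    sequence's bending ground truth and per-step tilt/roll columns with the
    local anisotropy (roll variance above tilt variance).
    """
    p = study_params(name, n_frames, seed)
    trajs = [gen_micro_trajectory(p, F) for F in forces]
    if with_bending:
        t0 = next(t for t in trajs if t.force == 0.0)
        lp_tau, lp_rho = BEND_TRUTH[name]
        Lbar = float(t0.u.sum(axis=1).mean())
        _, _, pair = gen_bend_series(lp_tau, lp_rho, Lbar, t0.n_frames,
                                     seed=p.seed + 7)
        triads = np.full((t0.n_frames, t0.n_bp, 3, 3), np.nan)
        triads[:, 0] = pair[:, 0]
        triads[:, -1] = pair[:, 1]
        t0.triads = triads
        rng = np.random.default_rng([p.seed, 991])
        shape = (t0.n_frames, t0.n_steps)
        t0.tilt = rng.normal(0.0, 3.0, shape)       # deg
        t0.roll = rng.normal(2.5, 5.0, shape)       # deg, locally softer
    return trajs
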