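"""Reading, validating and writing helical-parameter trajectories.

A trajectory holds, for every saved snapshot of one constant-force
simulation, the per-step helical parameters (rise, twist, optionally slide,
tilt, roll), the base-pair center geometry (centers and/or the
center-to-center distances ``u``), the pulling anchor distance ``d`` and the
base-pair reference frames needed for bending analysis.  Helical-parameter
extraction from atomic coordinates is upstream work (3DNA / CPPTRAJ); this
module only consumes its tabulated output.

Two on-disk formats are supported:

``canonical``
    A flat UTF-8 tab-delimited file with a commented metadata header and
    ``[steps]`` / ``[frames]`` / ``[centers]`` / ``[triads]`` sections.
    Written by :func:`write_trajectory`; round-trips bit-exactly.

``x3dna_steps``
    The classic 3DNA/CPPTRAJ "base-pair step parameters" listing with
    ``Shift Slide Rise Tilt Roll Twist`` columns (Ångström / degrees, one
    block per frame).  Extra columns are tolerated and ignored.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindow",
    "HelicalTrajectory",
    "TrajectoryError",
    "TrajectoryParseError",
    "TrajectoryStructureError",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
]


class TrajectoryError(Exception):
    """Base class for trajectory I/O and validation failures."""


class TrajectoryParseError(TrajectoryError):
    """Malformed file content (names the offending line where possible)."""


class TrajectoryStructureError(TrajectoryError):
    """Inconsistent array shapes, e.g. varying step count across frames."""


class TrajectoryValidationError(TrajectoryError):
    """A physical invariant is violated (negative rise, bad triads, ...)."""


_VALID_BASES = set("ACGT")

#: tolerance for ``u`` vs the norm of consecutive center differences (nm)
_U_CENTER_TOL = 1e-6


@dataclass(frozen=True)
class AnalysisWindow:
    """Contiguous base-pair window, 0-based inclusive indices.

    Step ``i`` joins base pairs ``i`` and ``i+1``; a window covering base
    pairs ``first..last`` therefore covers steps ``first..last-1``.
    """

    first: int
    last: int

    def __post_init__(self) -> None:
        if not (0 <= self.first < self.last):
            raise ValueError(
                f"window must satisfy 0 <= first < last, got [{self.first}, {self.last}]"
            )

    @property
    def n_bp(self) -> int:
        return self.last - self.first + 1

    @property
    def n_steps(self) -> int:
        return self.last - self.first

    @property
    def step_slice(self) -> slice:
        return slice(self.first, self.last)

    @property
    def bp_slice(self) -> slice:
        return slice(self.first, self.last + 1)

    def check(self, n_bp: int) -> None:
        if self.last >= n_bp:
            raise ValueError(
                f"window [{self.first}, {self.last}] exceeds n_bp={n_bp}"
            )

    @classmethod
    def central(cls, n_bp: int, size: int = 10) -> "AnalysisWindow":
        """The ``size`` central base pairs (default: the central decamer,
        i.e. external handles discarded)."""
        if n_bp < size:
            raise ValueError(f"n_bp={n_bp} smaller than window size {size}")
        first = (n_bp - size) // 2
        return cls(first, first + size - 1)


@dataclass
class HelicalTrajectory:
    """Per-snapshot, per-step helical parameters of one constant-force run.

    Angles (twist, tilt, roll) are stored in degrees as on disk; lengths in
    nm; force in pN; temperature in K.  Optional arrays are ``None`` when
    absent.  ``triads[f, b]`` is a 3x3 matrix whose *columns* are the
    base-pair axes in the lab frame (short axis, groove axis, helical axis);
    rows of NaN mark base pairs without a frame.
    """

    sequence: str
    force: float
    temperature: float
    rise: np.ndarray                       # (n_frames, n_steps)
    twist: np.ndarray                      # (n_frames, n_steps), degrees
    slide: np.ndarray | None = None        # (n_frames, n_steps)
    u: np.ndarray | None = None            # (n_frames, n_steps)
    center: np.ndarray | None = None       # (n_frames, n_bp, 3)
    anchor_distance: np.ndarray | None = None  # (n_frames,)
    triads: np.ndarray | None = None       # (n_frames, n_bp, 3, 3)
    triad_origins: np.ndarray | None = None    # (n_frames, n_bp, 3)
    tilt: np.ndarray | None = None         # (n_frames, n_steps), degrees
    roll: np.ndarray | None = None         # (n_frames, n_steps), degrees
    save_stride_note: str = ""

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_steps(self) -> int:
        return self.n_bp - 1

    @property
    def n_frames(self) -> int:
        return self.rise.shape[0]

    def step_sequence(self) -> list[str]:
        """Dinucleotide step labels, 5'->3' on the reference strand."""
        return [self.sequence[i : i + 2] for i in range(self.n_steps)]

    def __post_init__(self) -> None:
        self.rise = np.asarray(self.rise, dtype=float)
        self.twist = np.asarray(self.twist, dtype=float)
        for name in ("slide", "u", "center", "anchor_distance", "triads", "triad_origins", "tilt", "roll"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    def validate(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - _VALID_BASES:
            raise TrajectoryValidationError(f"invalid sequence {self.sequence!r}")
        self.sequence = seq
        if self.n_bp < 2:
            raise TrajectoryValidationError("need at least 2 base pairs")
        if self.temperature <= 0:
            raise TrajectoryValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.force < 0:
            raise TrajectoryValidationError(f"force must be >= 0 pN, got {self.force}")
        nf, ns = self.rise.shape if self.rise.ndim == 2 else (0, -1)
        if self.rise.ndim != 2 or ns != self.n_steps:
            raise TrajectoryStructureError(
                f"rise must have shape (n_frames, {self.n_steps}), got {self.rise.shape}"
            )
        if nf == 0:
            raise TrajectoryValidationError("empty trajectory (n_frames = 0)")
        for name in ("twist", "slide", "u", "tilt", "roll"):
            v = getattr(self, name)
            if v is not None and v.shape != (nf, self.n_steps):
                raise TrajectoryStructureError(
                    f"{name} must have shape ({nf}, {self.n_steps}), got {v.shape}"
                )
        if np.any(self.rise <= 0):
            raise TrajectoryValidationError("rise must be positive everywhere")
        if self.u is not None and np.any(self.u < 0):
            raise TrajectoryValidationError("u must be non-negative")
        if self.center is not None and self.center.shape != (nf, self.n_bp, 3):
            raise TrajectoryStructureError(
                f"center must have shape ({nf}, {self.n_bp}, 3), got {self.center.shape}"
            )
        if self.anchor_distance is not None and self.anchor_distance.shape != (nf,):
            raise TrajectoryStructureError(
                f"anchor_distance must have shape ({nf},), got {self.anchor_distance.shape}"
            )
        if self.triads is not None:
            if self.triads.shape != (nf, self.n_bp, 3, 3):
                raise TrajectoryStructureError(
                    f"triads must have shape ({nf}, {self.n_bp}, 3, 3), got {self.triads.shape}"
                )
            if self.triad_origins is not None and self.triad_origins.shape != (nf, self.n_bp, 3):
                raise TrajectoryStructureError("triad_origins shape mismatch")
        if self.center is not None:
            u_from_c = np.linalg.norm(np.diff(self.center, axis=1), axis=2)
            if self.u is None:
                self.u = u_from_c
            elif np.max(np.abs(self.u - u_from_c)) > _U_CENTER_TOL:
                raise TrajectoryValidationError(
                    "u column disagrees with base-pair centers by more than "
                    f"{_U_CENTER_TOL} nm (max deviation "
                    f"{np.max(np.abs(self.u - u_from_c)):.3g} nm)"
                )


# ---------------------------------------------------------------------------
# canonical format

def _fmt(x: float) -> str:
    # shortest decimal text that round-trips the IEEE double exactly
    return repr(float(x))


def write_trajectory(traj: HelicalTrajectory, path: str | Path) -> Path:
    """Write a trajectory in the canonical tab-delimited format."""
    path = Path(path)
    lines: list[str] = ["# dnaelastic-trajectory v1"]
    lines.append(f"# sequence = {traj.sequence}")
    lines.append(f"# force_pN = {_fmt(traj.force)}")
    lines.append(f"# temperature_K = {_fmt(traj.temperature)}")
    if traj.save_stride_note:
        lines.append(f"# note = {traj.save_stride_note}")

    cols = ["frame", "step", "rise_nm", "twist_deg"]
    arrays = [traj.rise, traj.twist]
    for name, col in (("slide", "slide_nm"), ("u", "u_nm"),
                      ("tilt", "tilt_deg"), ("roll", "roll_deg")):
        v = getattr(traj, name)
        if v is not None:
            cols.append(col)
            arrays.append(v)
    lines.append("[steps]")
    lines.append("\t".join(cols))
    nf, ns = traj.rise.shape
    for f in range(nf):
        for s in range(ns):
            row = [str(f), str(s)] + [_fmt(a[f, s]) for a in arrays]
            lines.append("\t".join(row))

    if traj.anchor_distance is not None:
        lines.append("[frames]")
        lines.append("frame\td_nm")
        for f in range(nf):
            lines.append(f"{f}\t{_fmt(traj.anchor_distance[f])}")

    if traj.center is not None:
        lines.append("[centers]")
        lines.append("frame\tbp\tcx_nm\tcy_nm\tcz_nm")
        for f in range(nf):
            for b in range(traj.n_bp):
                c = traj.center[f, b]
                lines.append("\t".join([str(f), str(b)] + [_fmt(x) for x in c]))

    if traj.triads is not None:
        lines.append("[triads]")
        hdr = ["frame", "bp", "ox_nm", "oy_nm", "oz_nm"]
        for ax in ("e1", "e2", "e3"):
            hdr += [f"{ax}{c}" for c in "xyz"]
        lines.append("\t".join(hdr))
        origins = traj.triad_origins
        for f in range(nf):
            for b in range(traj.n_bp):
                T = traj.triads[f, b]
                if np.any(np.isnan(T)):
                    continue
                o = origins[f, b] if origins is not None else np.zeros(3)
                row = [str(f), str(b)] + [_fmt(x) for x in o]
                for k in range(3):
                    row += [_fmt(x) for x in T[:, k]]  # column k = axis k
                lines.append("\t".join(row))

    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _parse_header(text: str) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    lineno = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    return meta, lineno


def _read_canonical(path: Path) -> HelicalTrajectory:
    text = path.read_text(encoding="utf-8")
    meta, _ = _parse_header(text)
    for key in ("sequence", "force_pN", "temperature_K"):
        if key not in meta:
            raise TrajectoryParseError(f"{path}: header is missing '# {key} = ...'")
    try:
        force = float(meta["force_pN"])
        temperature = float(meta["temperature_K"])
    except ValueError as exc:
        raise TrajectoryParseError(f"{path}: non-numeric header value ({exc})") from exc
    sequence = meta["sequence"]

    # split into sections
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        m = re.fullmatch(r"\[(\w+)\]", line.strip())
        if m:
            current = sections.setdefault(m.group(1), [])
            continue
        if current is None:
            raise TrajectoryParseError(f"{path}:{lineno}: data outside any [section]")
        current.append(line)
    if "steps" not in sections or len(sections["steps"]) < 2:
        raise TrajectoryParseError(f"{path}: missing or empty [steps] section")

    def table(name: str) -> pd.DataFrame:
        try:
            return pd.read_csv(io.StringIO("\n".join(sections[name])), sep="\t",
                               float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise TrajectoryParseError(f"{path}: bad [{name}] table ({exc})") from exc

    steps = table("steps")
    n_bp = len(sequence)
    n_steps = n_bp - 1
    frames = np.unique(steps["frame"].to_numpy())
    n_frames = len(frames)
    counts = steps.groupby("frame").size()
    if counts.nunique() != 1 or counts.iloc[0] != n_steps:
        raise TrajectoryStructureError(
            f"{path}: expected {n_steps} step rows per frame, got counts "
            f"{sorted(counts.unique())}"
        )
    steps = steps.sort_values(["frame", "step"])

    def grid(col: str) -> np.ndarray | None:
        if col not in steps.columns:
            return None
        return steps[col].to_numpy(dtype=float).reshape(n_frames, n_steps)

    anchor = None
    if "frames" in sections:
        fr = table("frames").sort_values("frame")
        if len(fr) != n_frames:
            raise TrajectoryStructureError(f"{path}: [frames] table length mismatch")
        anchor = fr["d_nm"].to_numpy(dtype=float)

    center = None
    if "centers" in sections:
        ct = table("centers").sort_values(["frame", "bp"])
        if len(ct) != n_frames * n_bp:
            raise TrajectoryStructureError(f"{path}: [centers] table length mismatch")
        center = ct[["cx_nm", "cy_nm", "cz_nm"]].to_numpy(dtype=float).reshape(n_frames, n_bp, 3)

    triads = origins = None
    if "triads" in sections:
        tt = table("triads")
        triads = np.full((n_frames, n_bp, 3, 3), np.nan)
        origins = np.full((n_frames, n_bp, 3), np.nan)
        fidx = tt["frame"].to_numpy(dtype=int)
        bidx = tt["bp"].to_numpy(dtype=int)
        origins[fidx, bidx] = tt[["ox_nm", "oy_nm", "oz_nm"]].to_numpy(dtype=float)
        for k, ax in enumerate(("e1", "e2", "e3")):
            col = tt[[f"{ax}x", f"{ax}y", f"{ax}z"]].to_numpy(dtype=float)
            triads[fidx, bidx, :, k] = col

    return HelicalTrajectory(
        sequence=sequence, force=force, temperature=temperature,
        rise=grid("rise_nm"), twist=grid("twist_deg"), slide=grid("slide_nm"),
        u=grid("u_nm"), center=center, anchor_distance=anchor,
        triads=triads, triad_origins=origins,
        tilt=grid("tilt_deg"), roll=grid("roll_deg"),
        save_stride_note=meta.get("note", ""),
    )


# ---------------------------------------------------------------------------
# 3DNA-style step-parameter listing

_X3DNA_COLS = ("shift", "slide", "rise", "tilt", "roll", "twist")


def _read_x3dna(path: Path, force: float | None, temperature: float | None,
                sequence: str | None) -> HelicalTrajectory:
    """Parse a (possibly concatenated, one block per frame) 3DNA bp_step table.

    Values are in Ångström / degrees per the 3DNA convention and converted to
    nm on ingestion.  Extra columns are ignored; metadata comes from leading
    ``# key = value`` comment lines or from keyword arguments.
    """
    text = path.read_text(encoding="utf-8")
    meta, _ = _parse_header(text)
    force = float(meta.get("force_pN", force if force is not None else np.nan))
    temperature = float(meta.get("temperature_K", temperature if temperature is not None else np.nan))
    if np.isnan(force) or np.isnan(temperature):
        raise TrajectoryParseError(
            f"{path}: force/temperature not in header comments; pass them explicitly"
        )
    blocks: list[list[tuple[str, list[float]]]] = []
    col_order: list[int] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        toks = line.split()
        lowered = [t.lower() for t in toks]
        if "rise" in lowered and "twist" in lowered:
            # header line -> starts a new frame block
            # numeric columns follow the index and step-label columns; the
            # header's leading 'step' token is not a data column
            names = [t.rstrip("()") for t in lowered if t != "step"]
            try:
                col_order = [names.index(c) for c in _X3DNA_COLS]
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}:{lineno}: incomplete step header ({exc})") from exc
            blocks.append([])
            continue
        if col_order is None:
            raise TrajectoryParseError(f"{path}:{lineno}: data before any step header")
        # data line: index, step label, then numeric columns
        try:
            label = toks[1]
            nums = [float(t) for t in toks[2:]]
            vals = [nums[i] for i in col_order]
        except (IndexError, ValueError) as exc:
            raise TrajectoryParseError(f"{path}:{lineno}: malformed step row ({exc})") from exc
        blocks[-1].append((label, vals))
    if not blocks or not blocks[0]:
        raise TrajectoryParseError(f"{path}: no step-parameter blocks found")
    n_steps = len(blocks[0])
    for i, blk in enumerate(blocks):
        if len(blk) != n_steps:
            raise TrajectoryStructureError(
                f"{path}: frame {i} has {len(blk)} steps, expected {n_steps}"
            )
    if sequence is None:
        # derive from step labels like 'GC/GC': chars 0-1 are bp i, i+1 bases
        labels = [lbl for lbl, _ in blocks[0]]
        try:
            sequence = labels[0][0] + "".join(lbl[1] for lbl in labels)
        except IndexError as exc:
            raise TrajectoryParseError(f"{path}: cannot derive sequence from labels") from exc
    data = np.array([[vals for _, vals in blk] for blk in blocks])  # (F, S, 6)
    ang_to_nm = 0.1
    return HelicalTrajectory(
        sequence=sequence, force=force, temperature=temperature,
        rise=data[:, :, 2] * ang_to_nm,
        twist=data[:, :, 5],
        slide=data[:, :, 1] * ang_to_nm,
        tilt=data[:, :, 3],
        roll=data[:, :, 4],
    )


def read_trajectory(path: str | Path, format: str = "canonical", *,
                    force: float | None = None, temperature: float | None = None,
                    sequence: str | None = None) -> HelicalTrajectory:
    """Read and validate a helical-parameter trajectory.

    Parameters
    ----------
    path : file path
    format : {"canonical", "x3dna_steps"}
    force, temperature, sequence
        Metadata overrides for the ``x3dna_steps`` format, which does not
        always carry them in-file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "canonical":
        return _read_canonical(path)
    if format == "x3dna_steps":
        return _read_x3dna(path, force, temperature, sequence)
    raise ValueError(f"unknown format {format!r}")


def subset(traj: HelicalTrajectory, frames: slice | np.ndarray) -> HelicalTrajectory:
    """A new trajectory restricted to the given frames."""
    def take(a):
        return None if a is None else a[frames]
    return replace(
        traj,
        rise=traj.rise[frames], twist=traj.twist[frames],
        slide=take(traj.slide), u=take(traj.u), center=take(traj.center),
        anchor_distance=take(traj.anchor_distance), triads=take(traj.triads),
        triad_origins=take(traj.triad_origins), tilt=take(traj.tilt),
        roll=take(traj.roll),
    )
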