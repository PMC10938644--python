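import numpy as np
import pytest

from dnaelastic import AnalysisWindow, read_trajectory, write_trajectory
from dnaelastic.trajio import (HelicalTrajectory, TrajectoryParseError,
                               TrajectoryStructureError,
                               TrajectoryValidationError)


def _assert_equal_traj(a, b):
    assert a.sequence == b.sequence
    assert a.force == b.force and a.temperature == b.temperature
    for name in ("rise", "twist", "slide", "u", "center", "anchor_distance",
                 "tilt", "roll"):
        va, vb = getattr(a, name), getattr(b, name)
        if va is None:
            assert vb is None
        else:
            np.testing.assert_array_equal(va, vb)
    if a.triads is None:
        assert b.triads is None
    else:
        mask = ~np.isnan(a.triads)
        np.testing.assert_array_equal(a.triads[mask], b.triads[mask])


class TestCanonicalRoundTrip:
    def test_simple(self, simple_traj, tmp_path):
        p = write_trajectory(simple_traj, tmp_path / "t.tsv")
        back = read_trajectory(p)
        assert back.n_frames == 2 and back.n_steps == 11
        _assert_equal_traj(simple_traj, back)

    def test_all_optional_fields_bit_exact(self, rich_traj, tmp_path):
        p = write_trajectory(rich_traj, tmp_path / "t.tsv")
        _assert_equal_traj(rich_traj, read_trajectory(p))

    def test_missing_slide_marked_absent(self, simple_traj, tmp_path):
        p = write_trajectory(simple_traj, tmp_path / "t.tsv")
        back = read_trajectory(p)
        assert back.slide is None

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_fixtures(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        nf, nbp = rng.integers(1, 6), rng.integers(2, 9)
        ns = nbp - 1
        traj = HelicalTrajectory(
            sequence="".join(rng.choice(list("ACGT"), nbp)),
            force=float(rng.uniform(0, 20)),
            temperature=300.0,
            rise=rng.uniform(0.2, 0.4, (nf, ns)),
            twist=rng.normal(34, 5, (nf, ns)),
            u=rng.uniform(0.2, 0.5, (nf, ns)),
        )
        p = write_trajectory(traj, tmp_path / "t.tsv")
        _assert_equal_traj(traj, read_trajectory(p))


class TestValidation:
    def test_u_center_disagreement(self):
        nf, nbp = 1, 3
        center = np.zeros((nf, nbp, 3))
        center[0, :, 2] = [0.0, 0.34, 0.68]
        with pytest.raises(TrajectoryValidationError, match="centers"):
            HelicalTrajectory(
                sequence="GCG", force=0.0, temperature=300.0,
                rise=np.full((nf, 2), 0.3), twist=np.full((nf, 2), 34.0),
                u=np.full((nf, 2), 0.44),  # disagrees by 0.1 nm
                center=center,
            )

    def test_u_derived_from_centers(self):
        center = np.zeros((1, 3, 3))
        center[0, :, 2] = [0.0, 0.34, 0.68]
        traj = HelicalTrajectory(
            sequence="GCG", force=0.0, temperature=300.0,
            rise=np.full((1, 2), 0.3), twist=np.full((1, 2), 34.0),
            center=center,
        )
        np.testing.assert_allclose(traj.u, 0.34)

    @pytest.mark.parametrize("bad", [
        dict(rise=-0.1), dict(u=-0.2), dict(temperature=-5.0),
        dict(force=-1.0), dict(sequence="ACGX"),
    ])
    def test_invariant_violations_rejected(self, bad):
        kw = dict(sequence="ACGT", force=0.0, temperature=300.0,
                  rise=np.full((2, 3), 0.34), twist=np.full((2, 3), 34.0),
                  u=np.full((2, 3), 0.35))
        for key, val in bad.items():
            if key in ("rise", "u"):
                arr = kw[key].copy()
                arr[0, 0] = val
                kw[key] = arr
            else:
                kw[key] = val
        with pytest.raises(TrajectoryValidationError):
            HelicalTrajectory(**kw)

    def test_inconsistent_step_count(self):
        with pytest.raises(TrajectoryStructureError):
            HelicalTrajectory(sequence="ACGT", force=0.0, temperature=300.0,
                              rise=np.full((2, 5), 0.34),
                              twist=np.full((2, 5), 34.0))

    def test_empty_trajectory_refused(self, tmp_path):
        with pytest.raises(TrajectoryValidationError, match="empty"):
            HelicalTrajectory(sequence="ACGT", force=0.0, temperature=300.0,
                              rise=np.zeros((0, 3)), twist=np.zeros((0, 3)))

    def test_malformed_header_names_problem(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# dnaelastic-trajectory v1\n# sequence = ACG\n[steps]\n")
        with pytest.raises(TrajectoryParseError, match="force_pN"):
            read_trajectory(p)

    def test_file_step_count_mismatch(self, simple_traj, tmp_path):
        p = write_trajectory(simple_traj, tmp_path / "t.tsv")
        lines = p.read_text().splitlines()
        del lines[7]  # drop one step row of frame 0
        p.write_text("\n".join(lines))
        with pytest.raises(TrajectoryStructureError):
            read_trajectory(p)


X3DNA_SAMPLE = """\
# force_pN = 5
# temperature_K = 300
    step       Shift     Slide      Rise      Tilt      Roll     Twist
   1 GC/GC     -0.04     -0.18      3.25     -1.23      5.12     32.45
   2 CA/TG      0.11      0.50      3.40      0.80      2.00     34.10
   3 AT/AT     -0.02     -0.30      3.31     -0.10      1.10     33.00
    step       Shift     Slide      Rise      Tilt      Roll     Twist
   1 GC/GC     -0.01     -0.20      3.30     -1.00      4.90     32.00
   2 CA/TG      0.09      0.45      3.38      0.70      2.10     34.50
   3 AT/AT     -0.03     -0.28      3.29     -0.20      1.00     33.10
"""


class TestX3dnaReader:
    def test_parses_blocks_and_units(self, tmp_path):
        p = tmp_path / "steps.par"
        p.write_text(X3DNA_SAMPLE)
        traj = read_trajectory(p, format="x3dna_steps")
        assert traj.n_frames == 2 and traj.n_steps == 3
        assert traj.sequence == "GCAT"
        assert traj.force == 5.0
        # Angstrom -> nm conversion on rise/slide, degrees kept
        assert traj.rise[0, 0] == pytest.approx(0.325)
        assert traj.slide[1, 1] == pytest.approx(0.045)
        assert traj.twist[1, 2] == pytest.approx(33.10)
        assert traj.roll[0, 0] == pytest.approx(5.12)

    def test_tolerates_extra_columns(self, tmp_path):
        txt = X3DNA_SAMPLE.replace("Twist", "Twist    Extra")
        txt = "\n".join(
            line + ("      9.99" if line.lstrip()[:1].isdigit() else "")
            for line in txt.splitlines())
        p = tmp_path / "steps.par"
        p.write_text(txt)
        traj = read_trajectory(p, format="x3dna_steps")
        assert traj.twist[0, 0] == pytest.approx(32.45)

    def test_missing_metadata_raises(self, tmp_path):
        p = tmp_path / "steps.par"
        p.write_text(X3DNA_SAMPLE.split("\n", 2)[2])
        with pytest.raises(TrajectoryParseError, match="force"):
            read_trajectory(p, format="x3dna_steps")


class TestAnalysisWindow:
    def test_central_decamer(self):
        w = AnalysisWindow.central(26)
        assert (w.first, w.last) == (8, 17)
        assert w.n_bp == 10 and w.n_steps == 9

    @pytest.mark.parametrize("first,last", [(-1, 5), (5, 5), (7, 3)])
    def test_invalid_windows(self, first, last):
        with pytest.raises(ValueError):
            AnalysisWindow(first, last)

    def test_window_exceeding_trajectory(self, simple_traj):
        with pytest.raises(ValueError):
            AnalysisWindow(0, 12).check(simple_traj.n_bp)
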