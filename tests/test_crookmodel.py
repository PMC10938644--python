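import math

import numpy as np
import pytest

from dnaelastic import (CrookCurve, StepTable, crook_contribution,
                        eval_crook_curve, fit_crook_curve, fit_step_table,
                        merge_step_tables, predict_stretch_modulus)
from dnaelastic.crookmodel import STEP_TYPES, canonical_step
from dnaelastic.elasticity import LinearFit, StepSlopes

# parameter scale of the published crookedness-stiffness law
A_TRUE, B_TRUE, D_TRUE = 2.9e5, 736.0, 12.8


def _curve_points(A=A_TRUE, B=B_TRUE, D=D_TRUE, noise=0.0, seed=0, n=12):
    rng = np.random.default_rng(seed)
    b0 = np.linspace(0.22, 0.55, n)
    k = A * np.exp(-D * b0) + B
    dk = noise * k
    if noise:
        k = k * (1 + noise * rng.standard_normal(n))
    return [(b, kk, dd) for b, kk, dd in zip(b0, k, dk)]


class TestCanonicalSteps:
    def test_ten_types(self):
        assert len(STEP_TYPES) == 10

    @pytest.mark.parametrize("step,canon", [
        ("TT", "AA"), ("GT", "AC"), ("CT", "AG"), ("AT", "AT"),
        ("TG", "CA"), ("CC", "GG"), ("TC", "GA"), ("GC", "GC"),
    ])
    def test_reverse_complement_identification(self, step, canon):
        assert canonical_step(step) == canon


class TestCrookCurve:
    def test_noiseless_recovery(self):
        c = fit_crook_curve(_curve_points(), seed=1)
        assert c.A == pytest.approx(A_TRUE, rel=1e-6)
        assert c.B == pytest.approx(B_TRUE, rel=1e-6)
        assert c.D == pytest.approx(D_TRUE, rel=1e-6)

    def test_noisy_recovery_within_3delta(self):
        c = fit_crook_curve(_curve_points(noise=0.05, seed=2), seed=3)
        assert abs(c.A - A_TRUE) < 3 * c.dA
        assert abs(c.B - B_TRUE) < 3 * c.dB
        assert abs(c.D - D_TRUE) < 3 * c.dD

    def test_flat_points_flagged_degenerate(self):
        pts = [(b, B_TRUE, 0.0) for b in np.linspace(0.2, 0.5, 8)]
        with pytest.warns(UserWarning, match="flat|degenerate"):
            try:
                fit_crook_curve(pts, seed=4)
            except RuntimeError:
                pytest.skip("flat input failed to converge (acceptable)")

    def test_eval_asymptote_and_intercept(self):
        c = CrookCurve(A=A_TRUE, B=B_TRUE, D=D_TRUE)
        assert eval_crook_curve(c, 5.0)[0] == pytest.approx(B_TRUE, rel=1e-9)
        assert eval_crook_curve(c, 0.0)[0] == pytest.approx(A_TRUE + B_TRUE)

    def test_eval_scalar_value(self):
        c = CrookCurve(A=A_TRUE, B=B_TRUE, D=D_TRUE)
        k, _ = eval_crook_curve(c, 0.30)
        assert k == pytest.approx(6969.0, abs=1.0)

    def test_csv_roundtrip(self, tmp_path):
        c = CrookCurve(A=A_TRUE, B=B_TRUE, D=D_TRUE, dA=1e4, dB=30.0, dD=0.5)
        c.to_csv(tmp_path / "c.csv")
        back = CrookCurve.from_csv(tmp_path / "c.csv")
        assert back.A == c.A and back.D == c.D and back.dB == c.dB


def _slopes(seq, k_by_step, u0_by_step, dk=100.0, du0=0.002):
    ns = len(seq) - 1
    fits = [LinearFit(slope=1e-5, intercept=0.34, delta_slope=0.0,
                      delta_intercept=0.0, r2=1.0) for _ in range(ns)]
    k = np.array([k_by_step[canonical_step(seq[i:i + 2])] for i in range(ns)])
    u0 = np.array([u0_by_step[canonical_step(seq[i:i + 2])] for i in range(ns)])
    return StepSlopes(parameter="u", step_index=np.arange(ns), fits=fits,
                      k=k, u0=u0, dk=np.full(ns, dk), du0=np.full(ns, du0))


class TestStepTable:
    def test_single_occurrence_identity(self):
        tab = fit_step_table([("ACA", _slopes("ACA", {"AC": 6000.0, "CA": 5000.0},
                                              {"AC": 0.34, "CA": 0.35}))])
        assert tab.k["AC"] == pytest.approx(6000.0)
        assert tab.u0["CA"] == pytest.approx(0.35)

    def test_two_occurrences_mean(self):
        s1 = _slopes("ACA", {"AC": 6000.0, "CA": 5000.0}, {"AC": 0.34, "CA": 0.35})
        s2 = _slopes("ACA", {"AC": 8000.0, "CA": 5000.0}, {"AC": 0.34, "CA": 0.35})
        tab = fit_step_table([("ACA", s1), ("ACA", s2)])
        assert tab.k["AC"] == pytest.approx(7000.0)

    def test_incomplete_table_lists_missing(self):
        tab = fit_step_table([("ACA", _slopes("ACA", {"AC": 6000.0, "CA": 5000.0},
                                              {"AC": 0.34, "CA": 0.35}))])
        with pytest.raises(ValueError, match="missing"):
            tab.require_complete()

    def test_merge_unweighted_mean(self):
        k = {s: 5000.0 for s in STEP_TYPES}
        u = {s: 0.34 for s in STEP_TYPES}
        t1 = StepTable(k=dict(k), u0=dict(u))
        t2 = StepTable(k={s: 7000.0 for s in STEP_TYPES}, u0=dict(u))
        merged = merge_step_tables([t1, t2])
        assert merged.k["AA"] == pytest.approx(6000.0)

    def test_unphysical_entries_rejected(self):
        with pytest.raises(ValueError):
            StepTable(k={"AA": -1.0}, u0={"AA": 0.34})
        with pytest.raises(ValueError):
            StepTable(k={"AA": 5000.0}, u0={"AA": 0.7})

    def test_csv_roundtrip(self, tmp_path):
        k = {s: 5000.0 + i for i, s in enumerate(STEP_TYPES)}
        u = {s: 0.34 for s in STEP_TYPES}
        t = StepTable(k=k, u0=u, dk={s: 10.0 for s in STEP_TYPES},
                      du0={s: 0.001 for s in STEP_TYPES})
        t.to_csv(tmp_path / "t.csv")
        back = StepTable.from_csv(tmp_path / "t.csv")
        assert back.k == t.k and back.du0 == t.du0


class TestPrediction:
    def _uniform(self, k_u, u0=0.34, n_steps=9):
        seq = "AC" * 5
        table = StepTable(k={"AC": k_u, "CA": k_u}, u0={"AC": u0, "CA": u0})
        return seq[:n_steps + 1], table

    def test_two_equal_series_springs(self):
        seq, table = self._uniform(3000.0)
        curve = CrookCurve(A=1.0, B=3000.0, D=1.0)  # k_beta ~ B at large b0
        S, _ = predict_stretch_modulus(seq, 20.0, curve, table)
        assert S == pytest.approx(1500.0, rel=1e-6)

    def test_rigid_crookedness_limit(self):
        seq, table = self._uniform(3000.0)
        curve = CrookCurve(A=1.0, B=1e12, D=1.0)
        S, _ = predict_stretch_modulus(seq, 20.0, curve, table)
        assert S == pytest.approx(3000.0, rel=1e-3)

    def test_compliances_add_identically(self):
        seq = "GCACATAAGA"
        rng = np.random.default_rng(0)
        k = {s: float(rng.uniform(4000, 9000)) for s in STEP_TYPES}
        u0 = {s: float(rng.uniform(0.32, 0.36)) for s in STEP_TYPES}
        table = StepTable(k=k, u0=u0)
        curve = CrookCurve(A=A_TRUE, B=B_TRUE, D=D_TRUE)
        beta0 = 0.35
        S, _ = predict_stretch_modulus(seq, beta0, curve, table)
        k_beta, _ = eval_crook_curve(curve, beta0)
        steps = [canonical_step(seq[i:i + 2]) for i in range(len(seq) - 1)]
        Lu = sum(u0[s] for s in steps)
        assert 1 / S - 1 / k_beta == pytest.approx(
            sum(u0[s] / k[s] for s in steps) / Lu, rel=1e-12)

    def test_monotone_in_stiffnesses(self):
        seq, table = self._uniform(3000.0)
        curve_soft = CrookCurve(A=1.0, B=2000.0, D=1.0)
        curve_stiff = CrookCurve(A=1.0, B=4000.0, D=1.0)
        S_soft, _ = predict_stretch_modulus(seq, 20.0, curve_soft, table)
        S_stiff, _ = predict_stretch_modulus(seq, 20.0, curve_stiff, table)
        assert S_stiff > S_soft
        _, table_stiff = self._uniform(6000.0)
        S2, _ = predict_stretch_modulus(seq, 20.0, curve_soft, table_stiff)
        assert S2 > S_soft

    def test_missing_step_rejected(self):
        table = StepTable(k={"AC": 5000.0}, u0={"AC": 0.34})
        curve = CrookCurve(A=A_TRUE, B=B_TRUE, D=D_TRUE)
        with pytest.raises(ValueError, match="missing"):
            predict_stretch_modulus("ACGT", 0.3, curve, table)


class TestCrookContribution:
    def test_limits(self):
        assert crook_contribution(3000.0, 3000.0) == 1.0
        assert crook_contribution(1500.0, 3000.0) == 0.5
        assert crook_contribution(10.0, 1e15) == pytest.approx(0.0, abs=1e-10)

    def test_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            assert crook_contribution(4000.0, 3000.0) == 1.0
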