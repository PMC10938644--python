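# dnaelastic

Stretch, twist and bending elasticity of short DNA duplexes from
helical-parameter trajectories.

## The problem

Single-molecule experiments and atomistic simulations describe the
mechanical response of double-stranded DNA through a small set of elastic
constants. For a duplex fragment of unstressed contour length *L₀* and
torsion *θ₀*, the harmonic extension–torsion energy is

```
E = (1 / 2L0) [ S ΔL² + C Δθ² + 2 g ΔL Δθ ] − F ΔL
```

with the stretch modulus *S* (pN), torsional modulus *C* (pN·nm²) and
twist–stretch coupling *g* (pN·nm). Constant-force MD simulations of short
duplexes provide per-snapshot helical parameters (3DNA definitions,
extracted upstream with CPPTRAJ or 3DNA itself); this package turns those
time series into the elastic description:

- **Effective stretch modulus** S̃ from the slope of ⟨ΔL⟩_F vs *F*
  (⟨ΔL⟩_F = L₀F/S̃), and equivalently S̃ = S − g²/C from the constants.
- **Fluctuation-based constants** at each force: the stiffness matrix is
  k_BT·L₀·Σ⁻¹, with Σ the covariance of (L, θ) in the force ensemble,
  giving S(F), C(F), g(F) and their trends dS/dF, dC/dF, dg/dF.
- **FEP reweighting**: the pulling protocol conjugates the force to the
  anchor distance *d*, not to the contour length *L*; snapshots are
  reweighted by exp[F(ΔL − Δd)/k_BT] to recover the contour-length
  ensemble, with block-analysis + weighted-bootstrap error bars (1000
  replicates, block weights = summed snapshot weights, final error averaged
  over the largest block sizes).
- **Crookedness model**: the crookedness β (cos β = L / Σᵢuᵢ, uᵢ the
  base-pair center–center distances) responds to force as
  ⟨cos β⟩_F = c₀(1 + F/k_β). Across sequences k_β collapses onto
  k_β(β₀) = A·exp(−D·β₀) + B, and the stretch modulus follows from a
  series of springs, 1/S̃ = 1/k_β + (1/L_u)·Σᵢ u₀ᵢ/kᵢ — predicting
  elasticity from sequence (tabulated step constants kᵢ, u₀ᵢ) and
  zero-force structure (β₀) alone.
- **Persistence lengths** from generalized tilt/roll fluctuations of the
  terminal base-pair frames: l_p^τ = L̄/Var(δτ), l_p^ρ = L̄/Var(δρ),
  combined as 1/l_p = (1/l_p^τ + 1/l_p^ρ)/2.

Since no MD trajectories ship with the package, a first-class synthetic
generator (`dnaelastic.synthgen`) produces harmonically fluctuating,
AR(1)-correlated trajectories with known ground truth, which every stage of
the analysis is validated against.

## Worked example

```python
from dnaelastic import (AnalysisWindow, RodParams, analyze_force_series,
                        gen_rod_trajectory)

params = RodParams(S=1200.0, C=430.0, g=-100.0, L0=3.4, n_frames=50_000,
                   seed=7, phi=0.3)
trajs = [gen_rod_trajectory(params, F) for F in (0, 1, 5, 10, 15, 20)]
report = analyze_force_series(trajs, window=AnalysisWindow(0, 10), seed=7,
                              n_boot=200, max_sizes=100)
print(report.to_text())
```

prints (abridged)

```
L0                 3.39994 +/- 0.000630 nm
S_eff (slope)      1177.53 +/- 16.0 pN
F = 0 pN  (ESS 50000)
  S_pN               1197.13 +/- 8.80 pN
  C_pNnm2            431.871 +/- 3.16 pN nm^2
  g_pNnm             -103.515 +/- 3.96 pN nm
  S_eff_pN           1172.32 +/- 8.26 pN
dS/dF              0.0820392 +/- 0.604
```

i.e. the slope route (1178 ± 16 pN) and the fluctuation route
(S − g²/C = 1172 ± 8 pN) agree with each other and with the generating
truth S̃ = 1200 − 100²/430 ≈ 1176.7 pN within errors, and no spurious
force-stiffening appears (dS/dF consistent with zero, as generated). The
effective sample size (ESS) column shows the FEP weights at work: at 20 pN
the anchor-distance ensemble still retains ~80% of its frames after
reweighting, the overlap regime the method requires.

The same workflow is available from the shell: `dnaelastic synth` writes
canonical trajectory files, `dnaelastic analyze --config study.yaml` runs
the full study and writes `report.json` / `report.txt`.

## The analysis scripts

`analysis/01_generate_study_set.py` … `04_bending.py` run the full
narrative on the default synthetic study set (six poly-XY repeats plus a
random-like 16-mer, forces 0–20 pN): raw observables, per-sequence elastic
constants and force trends, the crookedness law + step table + stretch
prediction, and persistence lengths. Each writes its tables under
`results/`.

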