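# Methods

## Scope and data model

The package analyses per-snapshot helical parameters of a short DNA duplex
simulated at constant pulling force. It does not compute helical
parameters from atomic coordinates: that step belongs to 3DNA/CPPTRAJ, and
the package consumes their tabulated output, either in its own canonical
tab-delimited format or in the classic 3DNA step-parameter listing
(Ångström/degree columns, converted to nm on ingestion). Units are fixed at
pN, nm, K and degrees-on-disk; twist is converted to radians exactly once,
in the observables layer, so that the torsional modulus carries pN·nm²
consistently with k_B T in pN·nm. k_B is the exact SI value,
0.01380649 pN·nm/K (k_BT = 4.14195 pN·nm at 300 K); fixing it removes a
silent unit ambiguity between data sources.

Base pairs are 0-indexed; step *i* joins base pairs *i* and *i*+1. For
real trajectories with handles the default analysis window is the central
ten base pairs; the synthetic generators emit already-trimmed windows, which
are analysed in full.

## Observables

Per frame, the extension is the sum of helical rises over the window,
L = Σ rise_i; the torsion θ = Σ twist_i (radians); the center-line contour
is Σ u_i with u_i the euclidean distance between consecutive base-pair
centers; and the crookedness β is defined by cos β = L / Σ u_i, the angle
measuring how far the base-pair centers wander off the helical axis (β = 0:
perfectly aligned centers). L = cos β · Σu holds identically by
construction. A frame with summed rise exceeding the summed center distance
(cos β > 1 beyond 1e-9) is a validation error, not a clamp.

### Generalized tilt and roll

Global bending is measured between the first and last base-pair frames of
the window: the relative rotation is taken in rotation-vector
(matrix-logarithm) form and its components are read off in the mid-frame
(the geodesic midpoint of the two orientations). The component along the
mid-frame short axis is the generalized tilt τ (bending toward the
backbone), the component along the groove axis the generalized roll ρ; the
twist component is discarded. The published formulation of this operator is
not printed in a machine-readable form, so the mid-frame rotation-vector
decomposition — the standard choice, exactly equivariant under global
rotations — is adopted and isolated behind a single function
(`observables.rotation_bend_decomposition`) so an alternative convention
can be swapped in.

## FEP reweighting

The simulation protocol applies the force along the line joining the pulled
anchors, so the ensemble sampled is governed by Ē(F) = E(F) − F(Δd − ΔL),
with d the anchor distance. Averages in the contour-length ensemble E(F)
follow by weighting each snapshot with exp[F(ΔL − Δd)/k_BT]; additive
constants in L and d cancel on normalization (asserted in tests), so raw
values are used. Weights are computed after subtracting the maximum
exponent (overflow guard) and normalized to mean 1. The effective sample
size ESS = (Σw)²/Σw² is reported; ESS below 10% of the frame count triggers
an overlap warning, since the method presumes the pulled and target
ensembles overlap appreciably. Each force is reweighted to itself only —
no multi-state (MBAR-style) combination across forces.

## Error analysis

Errors of weighted averages and fluctuations come from block analysis with
a weighted bootstrap: frames are partitioned into consecutive blocks, each
bootstrap replicate draws blocks with replacement with probability
proportional to the block's summed FEP weight, the weighted statistic is
recomputed, and the error at that block size is the standard deviation over
1000 replicates. The final error averages the error over the largest 200
block sizes of the scan.

Unstated conventions were fixed as follows:

- **Grid**: every integer block size from 1 to n/50, uniformly subsampled
  to at most 400 sizes. The n/50 cap keeps at least 50 blocks at every
  size; with fewer blocks the empirical variance of the block means carries
  χ² noise of tens of percent plus the (m−1)/m bootstrap bias, which would
  dominate the plateau average. The cap presumes the correlation time is
  well below n/500 frames — comfortably true for typical MD snapshot
  strides and for the AR(1) generators here (calibration: an AR(1) series
  with lag-1 correlation 0.9 and n = 1e5 reproduces the analytic correlated
  SEM to within a few percent, well inside the 20% band the tests assert).
- **Partial blocks**: the trailing partial block is discarded, so
  weight-proportional block sampling is not distorted by unequal lengths.
- **Weighted variance**: central second moments use the FEP weights with no
  Bessel-type correction; at the frame counts involved (1e4–1e6) the bias
  is negligible.
- **Determinism**: all resampling streams derive from one seed via
  NumPy `SeedSequence` spawning, one child per block size; reruns are
  bit-identical.

Fit errors follow a two-channel protocol: δ_ave from the standard
least-squares parameter covariance, and δ_ind from 1000 seeded Monte-Carlo
resamples of the fitted points perturbed by their individual error bars
(normal), refit, with the spread of the coefficients taken as the error;
the two channels combine in quadrature, δ = √(δ_ave² + δ_ind²). Force
responses are fitted unweighted in y — the point errors enter only through
the δ_ind channel, mirroring the two-channel protocol rather than a
weighted regression. Derived ratios (k_β = c₀/slope, k_i = u₀ᵢ/slope)
propagate the sampled slope–intercept covariance from the same Monte-Carlo
resamples.

## Elastic constants

Slope route: ⟨ΔL⟩_F = L₀F/S̃ gives S̃ = L₀/slope;
⟨cos β⟩_F = c₀(1 + F/k_β) gives the crookedness stiffness k_β = c₀/slope
and zero-force extrapolation c₀ ∈ (0, 1]. A slope at floating-point zero is
reported as the rigid limit (k_β = +∞ sentinel); a negative slope is an
error, since pulling must decrease crookedness.

Fluctuation route: with Σ the weighted covariance of (L, θ) in the force
ensemble, the stiffness matrix of the quadratic energy is K = k_BT·L₀·Σ⁻¹,
i.e. S = k_BT·L₀·Var(θ)/detΣ, C = k_BT·L₀·Var(L)/detΣ,
g = −k_BT·L₀·Cov(L, θ)/detΣ. S̃ = S − g²/C is the closed form obtained by
minimising the energy over the torsion at fixed force, exposed as one
function so an alternative convention could be swapped. L₀ (and θ₀) are
the weighted means of the F = 0 ensemble, and the same zero-force L₀ is
used in the fluctuation formulas at F > 0: the quadratic energy fixes L₀
as the unstressed length, and whether the source convention uses ⟨L⟩_F
instead is not documented; at the forces considered the difference is
below 1%. Non-positive-definite covariances (detΣ ≤ 0) and zero variances
are errors, not silent outputs. First-order error propagation runs from
block-bootstrap errors of the three covariance entries through analytic
partial derivatives.

Force trends S(F), C(F), g(F) are fitted linearly with the same two-channel
errors. Per-step force responses (⟨u_i⟩_F = u₀ᵢ(1 + F/k_i), and slide/rise/
twist slopes) use FEP-weighted per-force means; their point errors default
to an ESS-corrected weighted SEM rather than a full per-step block
bootstrap — with ten steps and six forces the bootstrap cost would dominate
the study for a second-order refinement of error bars — and the full block
bootstrap remains available via `error_method="block"`.

## Crookedness model

The empirical stiffness law k_β(β₀) = A·e^(−Dβ₀) + B is fitted by
multistart nonlinear least squares (decay-rate starts spanning a decade and
a half; convergence judged on residual sum of squares, positivity of all
three parameters required). β is in radians throughout; because the
calibration unit of the published D is not stated, the unit is an explicit
knob on the curve object (`beta_unit`). The series-of-springs prediction

1/S̃ = 1/k_β + (1/L_u)·Σᵢ u₀ᵢ/k_i,  L_u = Σᵢ u₀ᵢ

is the first-order expansion of ⟨L⟩_F = ⟨cos β⟩_F · Σ⟨u_i⟩_F in F; the
compliance-additivity identity and its monotonicity in every stiffness are
asserted in tests. The per-step table aggregates (k_i, u₀ᵢ) over all
occurrences across sequences by unweighted mean (the source protocol states
no weights), with errors combining the spread across occurrences and the
propagated individual errors in quadrature; tables from different force
fields merge by the same unweighted-mean rule. The crookedness share of the
stretch compliance is (1/k_β)/(1/S̃) = S̃/k_β, clipped to [0, 1] with a
warning. Tetranucleotide context dependence of step stiffness is out of
model scope.

## Persistence lengths

l_p^τ = L̄/Var(δτ) and l_p^ρ = L̄/Var(δρ), with mean-subtracted angles so
intrinsic curvature does not deflate the estimate, and L̄ the time-averaged
center-line contour length of the window. The overall persistence length is
the harmonic mean, 1/l_p = (1/l_p^τ + 1/l_p^ρ)/2 — exact by construction.
The 1/Var normalization of the length-dependent elastic model is assumed
(the source prints the formulas only graphically) and isolated in one
function. Zero variance returns an infinite-persistence sentinel. A
complementary per-step operation reports local tilt/roll variances and
flags steps where roll fluctuates more than tilt — locally the anisotropy
inverts relative to the fragment level.

## Synthetic generators

The generators emulate the statistical structure the estimators assume, so
parameter recovery is a meaningful end-to-end test:

- **Harmonic rod**: (L, θ) drawn from the stationary Gaussian of the
  quadratic energy at force F — mean shift (F·L₀·C/(SC−g²),
  −F·L₀·g/(SC−g²)), covariance k_BT·L₀·K⁻¹ — with componentwise AR(1)
  memory (default lag-1 correlation φ = 0.8, emulating the autocorrelation
  of MD snapshots saved every fixed number of steps, and making the block
  analysis genuinely non-trivial). L is spread over ten equal rises, θ over
  ten equal twists; u = rise/cos β₀ with constant crookedness. An optional
  dS/dF knob makes S force-dependent for stiffening-recovery tests.
- **Microstructure**: per-step u_i as AR(1) Gaussians with mean
  u₀ᵢ(1 + F/k_i) and equipartition variance k_BT·u₀ᵢ/k_i; cos β as an
  AR(1) Gaussian with mean c₀(1 + F/k_β), truncated to (0, 1] by redrawing
  violators (rate monitored, warning above 1%); rise_i = cos β·u_i so
  L = cos β·Σu exactly. The default noise scale of cos β is
  equipartition-consistent with k_β, and the default step constants put
  S̃ in the 1–4 × 10³ pN range with the AA step stiffest.
- **Anchor distance**: d = L + ε with harmonic noise ε (default SD
  0.1 nm). Because the pulled ensemble conjugates F to d, ε acquires the
  tilt mean F·σ_d²/k_BT under Ē(F); the generator includes that shift, so
  FEP weights are genuinely non-uniform (ESS < n) and reweighting
  measurably restores the E(F) statistics — the property the FEP tests
  assert. With the default parameters the width of the L distribution
  exceeds the full 1→20 pN mean shift, the stated overlap regime.
- **Bending**: i.i.d. tilt/roll angles with Var = L̄/l_p per mode, plus
  terminal triads realising the drawn rotation vector exactly (the first
  frame is the identity), so the decomposition round-trip is exact.

What the generators do *not* emulate: sequence-dependent twist
correlations beyond per-step Gaussians, anharmonicity, force-induced
melting or flipping events, and the slow collective modes of real MD whose
correlation times can rival the trajectory length. Passing recovery tests
therefore validates the estimator chain, not the force fields; on real
data the block-analysis plateau and the FEP overlap diagnostics must be
inspected, which is why both are first-class outputs.

## Study sizes and defaults

The synthetic acceptance studies use 1–2 × 10⁵ frames per force (2 × 10⁵
for zero-force covariance recovery), 1000 bootstrap replicates and the full
400-size block grid; the narrative analysis scripts use 2 × 10⁴ frames per
force with 200 replicates, sizes at which every recovery stays within its
quoted uncertainty while a full seven-sequence study completes in minutes
on one core. Default forces are 0, 1, 5, 10, 15, 20 pN at 300 K.

## Known limitations

- The x3dna_steps reader ingests rise/slide/tilt/roll/twist but no
  base-pair centers, so crookedness analysis from that format requires the
  canonical format (or centers supplied separately).
- Error propagation treats the three covariance entries (and the step-table
  entries) as independent; their cross-correlations are neglected.
- The fluctuation formulas assume a positive-definite 2×2 covariance;
  near-degenerate sampling (very short trajectories) fails loudly rather
  than regularising.
- Persistence lengths use the small-fluctuation 1/Var forms; strongly bent
  fragments (Var ≳ 0.1 rad²) would need the full length-dependent model.
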