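# Methods

## Model

Local SAR in a voxel is `s† Q s` for the complex channel drive `s`
(amplitudes in √W, so `‖s‖²` is the total forward power) and a Hermitian
positive-semidefinite Q-matrix in W/kg per W. Q is assembled as
`(σ/2ρ)(Ẽx†Ẽx + Ẽy†Ẽy + Ẽz†Ẽz)` from the per-channel complex field maps
(V/m for 1 W excitation) and is therefore a sum of three rank-1 terms:
`rank(Q) ≤ 3` for any channel count. Regulatory limits apply to SAR
averaged over a region containing 10 g of tissue; averaging is linear in
Q, so the averaged matrices keep every structural property.

**10g averaging dialect.** For each body voxel we grow an odd-sided cube
centered on the voxel (clipped at the grid boundary) until the enclosed
tissue mass reaches 10 g, then average entries with voxel-mass weights
over body voxels only; air contributes neither mass nor SAR. Voxels whose
largest clipped cube never reaches the target are excluded and logged.
This is the simple cubical dialect; IEC 62704-1 fractional-shell
interpolation is deliberately not implemented — it shifts absolute values
slightly but leaves the maximization machinery untouched.

## Worst-case maximization

With amplitudes fixed, SAR is a linear combination of cosines of phase
differences, so all local maxima are periodic copies along the global
phase direction and each coordinate has the closed-form maximizer
`φ_l = atan2(Y_l, X_l) = arg(c_l)`, `c_l = Σ_{m≠l} Q_lm s_m e^{iφ_m}`.
Both the coefficient form (the `A_x`, `A_y` tables in `TrigMaxState`) and
the complex form are implemented and tested for equality; the batched
driver uses the complex form.

Two sweep schemes are available:

- `jacobi` (default): all channels updated from the previous sweep's
  phases.
- `gauss_seidel`: in-place updates; each sweep is then an exact block
  coordinate ascent, so the SAR history is monotone and the iteration
  cannot cycle.

Both schemes share fixed points and are asserted to reach the same value.
The simultaneous scheme can, on symmetric inputs, fall into a 2-cycle
(SAR change vanishes while the gradient does not) or orbit without
settling; the driver detects the former via a gradient check at the
stopping test and falls back to `gauss_seidel` for any matrix still
unconverged after `jacobi_fallback_after` (default 100) sweeps. In-place
sweeps also converge far faster in practice — exponentially, reaching
relative error ≤ 1e-16 in ~7–10 sweeps on phantom-derived matrices —
which is why the convergence study below uses them.

**Stopping.** Iterate until `|ΔSAR| ≤ max(ε, ε_rel·SAR)` with at least two
sweeps; defaults ε = 1e-6 W/kg, ε_rel = 1e-12. An optional `grad_tol`
additionally requires `‖∇SAR‖∞` below a threshold before stopping: near a
maximum the SAR error is quadratic in the phase error, so SAR-change
stopping alone leaves a gradient of order √ΔSAR, and stationarity
certificates at 1e-8 need the explicit criterion.

**Maxima, not minima.** A stationary point is accepted only if the phase
Hessian (which is always singular along the all-ones global-phase
direction) has no meaningful positive curvature; otherwise the phases are
perturbed by 1e-3 rad from a seeded generator and iteration continues
(bounded retries). Such non-maximum fixed points are reachable only from
measure-zero starts, e.g. all-zero phases on a real matrix with negative
off-diagonal entries. The returned SAR never falls below the
initial-phase SAR (best-seen tracking), and reported phases are
normalized so the first driven channel has phase zero; undriven channels
report zero and are excluded from updates.

## Comparator estimators

- **TP**: `max_j λ_max(Q_j) · P_tot`. Tight exactly when the amplitude
  magnitudes are proportional to the dominant eigenvector's and the phases
  match it.
- **RP**: `min_k ζ_k · max_j w_k†Q_j w_k` with `w_k` the drive amplitudes
  carrying the k-th reference phases, capped at the TP bound of the same
  total power (per-drive cap). Defaults: K = 2 reference sets — all zeros
  and the circularly-polarized ramp `2πn/Nc`; suitable reference phases
  are array-dependent, so sets are user-configurable. Correction factors
  are calibrated with the trigonometric maximizer as the exact inner
  oracle: `ζ_k = max` over sampled amplitude sets of the ratio of the
  exact worst case to the reference-phase peak, with amplitudes sampled
  uniformly (in power) on the simplex from a seeded generator. This is
  conservative by construction on the sampled family; conservativeness on
  held-out drives is verified by Monte-Carlo tests, not guaranteed.
- **LB/UB**: quadratic form at the dominant-eigenvector phases (never
  above the worst case) and the all-magnitudes sum (never below). Both
  collapse to the exact worst case for rank-1 or diagonal matrices, and
  agree with it to a few percent whenever the dominant eigenvalue carries
  nearly all of the trace — the regime that holds near array elements,
  where peaks usually sit.

Overestimation is reported as `(estimate − actual)/actual` in percent.

## VOP compression

A matrix is dominated by a VOP `V` when `V + δ·λ̄·I − Q ⪰ 0` with `λ̄` the
largest eigenvalue over the whole set and δ the allowed overestimation
fraction (default 0.05). Compression is a greedy first-fit pass in
descending-λ_max order (ties by voxel index): a matrix joins the VOP list
unless an existing VOP dominates it; the dominating VOP is recorded per
voxel. PSD dominance gives, for every drive, conservativeness plus excess
at most `δ·λ̄·P_tot`. δ is applied to the global maximum eigenvalue — a
per-matrix reading would be tighter but is not what the stated rule says.
The pass makes no attempt at a minimal VOP count; counts depend strongly
on the spatial correlation of the input set (i.i.d. random matrices
barely compress, phantom-derived sets compress well).

## Synthetic data

The phantom generator is an **analytic surrogate, not a field solution**:
channel elements sit on a cylinder (or flat former) around a homogeneous
lossy cylinder (σ = 0.5 S/m, ρ = 1000 kg/m³, muscle-like), each
producing a field with magnitude `E0·exp(−d/L)` (default L = 4 cm,
E0 = 60 V/m·√W⁻¹) and propagation phase `−2πd/λ` (λ = 12 cm, a
tissue wavelength at ultra-high field). The `dominant_z` parameter sets
the power fraction in the z-component (default 0.9, dipole-like; 1.0
gives exactly rank-1 matrices everywhere); the transverse remainder
points radially from the element for dipole-like and azimuthally for
loop-like models. Defaults: 24×24×12 grid at 1 cm voxels, 8 channels.
What this reproduces: smooth per-channel phase variation, rank ≤ 3,
a dominant eigenvalue near elements (dominant fraction ≈ 0.97 at the
hottest voxels), realistic compression behavior. What it does not:
tissue heterogeneity, standing-wave structure, actual W/kg magnitudes of
any particular array — so passing tests validate the maximization and
bounding machinery, not absolute dosimetry.

Random Q ensembles are sums of `rank ≤ 3` outer products of complex
Gaussian vectors with geometrically decaying weights (ratio 0.3 by
default), optionally concentrated on single channels to emulate diagonal
dominance while preserving the rank bound (an added diagonal would break
it). Random drives have per-channel power uniform on the simplex (a flat
Dirichlet) and phases uniform on (−π, π]; the power distribution of real
examinations is unknown, so quantities that depend on it (mean
overestimation percentages) are treated as qualitative.

**Oracle.** `brute_force_max` fixes the global phase (φ₁ = 0) and scans
the remaining phases on a uniform grid, then polishes the best node by
L-BFGS ascent with the analytic gradient. On a uniform grid all pairwise
phase differences lie on the grid, so the SAR surface decomposes into 1-D
tables indexed by index differences; this makes a 720-point grid at
Nc = 4 cost ~1 s instead of 720³ scalar evaluations. Nc ≤ 5 only; the
multistart gradient-ascent oracle covers larger arrays.

## Numerical choices

- Hermitian enforcement: incoming matrices are symmetrized `(Q+Q†)/2`
  after checking the asymmetry norm ≤ 1e-8·‖Q‖; PSD checks use
  min-eigenvalue ≥ −1e-10·λ_max.
- Eigenvector phases are normalized so the first non-negligible component
  is real positive (removes the global eigenvector phase).
- Degenerate coordinate updates (Y = X = 0: undriven or fully decoupled
  channels) keep the previous phase and are flagged.
- Grid coordinates are 0-based voxel indices on (x, y, z); positions in
  meters; all SAR quantities in W/kg for the stated drive power.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data sized for a desktop: 100 oracle comparisons per channel count at a
720-point grid, 10⁴-drive Monte-Carlo audits on 200–500-matrix sets,
50-drive convergence studies on the 200 hottest phantom voxels. These
sizes are the package's validation conditions; the algorithms themselves
are vectorized over matrices and scale linearly in the set size.

## Known limitations

- The cubical 10g average is not IEC 62704-1 conformant (documented
  simplification).
- RP conservativeness holds by construction only on the calibration
  family; deployment would calibrate on the amplitude family of the
  actual system.
- The simultaneous (jacobi) sweep is kept as the default update scheme
  for fidelity to the classical statement of the fixed point, but its
  convergence is linear and not guaranteed; the gauss_seidel fallback
  makes the implementation robust, and users wanting monotone fast
  convergence should select `sweep_scheme="gauss_seidel"` directly.
- One sub-claim of the convergence study — median relative accuracy 1e-3
  after a single sweep — lands at ~1.2e-3–8e-3 on the default phantom:
  its peak voxels have dominant eigenvalue fraction ≈ 0.97, and the
  one-sweep error scales with the subdominant eigenvalue share, so arrays
  with a more dominant field component converge still faster. The
  machine-precision-in-≤10-sweeps behavior is reproduced.
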