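# Methods

This note records the models, numerical procedures and design choices
behind `fracvent`, in the spirit of a methods appendix: what is
computed, under which assumptions, and where the genuinely open choices
were resolved.

## Lung ladder model

The respiratory tree is modelled as an `N = 24` generation RC ladder.
Generation `m` (1-based everywhere in documentation; storage is
0-based) contributes a series airway resistance `R_m` and a shunt
constant-phase element `1/(C_m s^α)` for the viscoelastic tissue.
Because flow halves at each bifurcation, per-generation values derive
from single-branch values as `R_m = R*_m / 2^(m−1)`,
`C_m = 2^(m−1) C*_m`, where `R*`, `C*` follow a geometric recursion
with factor pair (2.476, 0.577) for transitions `m = 1..13`
(conducting airways) and (2.334, 0.613) for `m = 14..23` (acinar
region). Root values are the forced-oscillation estimates
`R_UA = 0.2834 kPa·s/l`, `C_UA = 0.0950 l·s^(α−1)/kPa`, `α = 1.55`,
identified in the 0.9–6 Hz band — which bounds the frequency range over
which the model (and any passband statement about it) is trustworthy.

Units are fixed project-wide: pressure kPa, flow l/s, time s; the
480 ml/s setpoint is stored as 0.48 l/s. The printed pseudo-capacitance
value is used as-is; no attempt is made to reconcile the `s^(α−1)`
versus `s^α` unit conventions for CPEs, since only the numeric products
`R_m C_m` enter the dynamics.

Kirchhoff's node equations give a tridiagonal `A`, `B = [1/(R₁C₁); 0;
…]`, `C = [−1/R₁, 0, …]`, `D = [1/R₁]`. Structural invariants used as
oracles: rows 2..N of `A` sum to zero and `A·1 = −B` (charge
conservation), hence a constant pressure settles to `x = u·1` with zero
flow — the admittance zero at `s = 0`. Scaling every `R_m` by `ρ_R` and
`C_m` by `ρ_C` is exactly a perturbation of `(R_UA, C_UA)` and maps the
matrices as `A/(ρ_R ρ_C)`, `B/(ρ_R ρ_C)`, `C/ρ_R`, `D/ρ_R`; the
Monte-Carlo study relies on this equivalence.

`x` is a *pseudo*-state: the true state of a fractional system is
infinite-dimensional. All simulations start from null initial
conditions, where the Caputo, Riemann–Liouville and Grünwald–Letnikov
derivatives coincide. Frequency responses use the principal branch of
`(jω)^α` for `ω ≥ 0`; negative frequencies follow by conjugate
symmetry.

## Stability and the placement region

Asymptotic stability of `D^α x = Ax` for `α ∈ (0,2)` is equivalent to
every eigenvalue of `A` lying in the sector `F(α) = {λ : |arg λ| >
απ/2}`; `λ = 0` is always rejected. Performance shaping uses the LMI
region `S(r, θ)` — open disk of radius `r` about the origin intersected
with the left cone of half-angle `θ`. Membership is decided directly by
`|λ| < r` and `Re(λ) sin θ + |Im(λ)| cos θ < 0`. For `α ∈ (1, 2)`,
`S(r, θ) ⊂ F(α)` iff `θ ≤ π − απ/2` (40.5° at `α = 1.55`); the design
pipeline rejects wider sectors before any solve.

`A` is `S(r, θ)`-stable iff there exists `X = Xᵀ ≻ 0` with

    [[−rX, AX], [XAᵀ, −rX]] ≺ 0,
    [[(AX+XAᵀ)sin θ, (AX−XAᵀ)cos θ], [(−AX+XAᵀ)cos θ, (AX+XAᵀ)sin θ]] ≺ 0.

Substituting `AX − BM` for `AX` and recovering `K = MX⁻¹` yields the
state-feedback synthesis condition; the observer gain comes from the
dual pair `(Aᵀ, Cᵀ)` (the standard reading — the region characterization
itself is direction-agnostic). The observer region defaults to the
controller region and is configurable independently.

## LMI feasibility engine

No semidefinite-programming library is part of the runtime stack, so
feasibility is decided by two in-package routes, both audited by an
exact `λ_max` computation on the assembled LMIs:

1. **Smoothed spectral minimization.** The LMIs are linear in `(X, M)`,
   so strict feasibility is equivalent to the convex function
   `f(X, M) = λ_max(blkdiag(F_disk, F_sector, δI − X))` attaining a
   negative value (`δI − X` fixes the scale of the homogeneous problem;
   `δ = 10⁻³` after normalizing the disk to unit radius and the input
   columns to unit norm). `f` is minimized through its log-sum-exp
   smoothing with analytic gradients (L-BFGS, τ-continuation over
   16…65536). A point with exact `f < 0` certifies feasibility; a
   converged positive minimum certifies infeasibility up to the
   smoothing gap `log(m)/τ`. In-between outcomes are reported as
   `inconclusive`, never as a silent pass.
2. **Constructive certificate.** If `A` is diagonalizable with spectrum
   strictly inside `S(r, θ)`, then `X = V diag(s) V^H` (real for real
   `A`) satisfies the region LMIs, because the LMI value is congruent
   to a direct sum of the scalar characteristic functions
   `s_i f_D(λ_i)`. Choosing `s_i = 1/|margin_i|` equalizes per-mode
   margins, which keeps the certificate verifiable in double precision
   even for the lung spectra spanning ~six decades. The route declines
   (returns nothing) for defective or ill-conditioned eigenstructures —
   e.g. the open-loop integrator chain has a Jordan block at `−ε` — and
   the spectral route then decides.

Synthesis tries the spectral route first (it returns interior-point-
like gains for well-conditioned problems). When the feasible margin is
below the solver's resolution — the lung's augmented plant has open-loop
modes at `~−6·10⁻⁴`, so any certificate margin is of that order —
heuristic region-placing gains are tried in sequence (an LQR family
over a grid of control weights, real-axis pole placement, zero gain)
and the first candidate whose closed spectrum lies strictly in the
region is certified through the constructive route with `M = KX`.
Every returned gain is additionally post-verified by the direct
eigenvalue membership test; a post-verification failure raises even if
a solver accepted the solution. Certificates `(X, M)` are kept in the
feasibility report for audit.

Gain matrices solving these LMIs are far from unique: independent
solvers produce different `K`, `L` with the same qualitative placement.
The published gain set is therefore shipped as a fixture (verbatim,
5-decimal truncation preserved) and used for all performance
measurements; `design_gains` demonstrates that the synthesis pipeline
reproduces the qualitative result (all 50 closed-loop eigenvalues in
`S(200, 5°)`).

Controllability is checked with the eigenvector (PBH) test rather than
the Kalman rank matrix: the controllability matrix of the 24-stage
ladder spans ~40 decades and its rank is not decidable in double
precision, while the PBH pencils stay well scaled. The rank threshold
is `n · σ_max · ε_machine`.

## Controller architecture

The plant's admittance zero at `s = 0` means a constant-pressure input
produces zero steady flow, so tracking a constant flow setpoint needs
double integral action — but *pure* double integrators would cancel
that zero and destabilize the loop. Both integrators therefore leak
with a single scalar `ε = 0.1` (a two-`ε` variant is accepted in
configuration), trading a small steady-state error for stability. The
reference enters scaled by `1 + K_r` with `K_r = 500`.

State ordering of the assembled closed loop is `[x; w1; w2; x̃]` with
`x̃ = x − x̂`, matching the block-triangular separation structure: the
nominal spectrum is exactly `eig(A − LC) ⊎ eig(A_xwr − B_xwr K_xw)`.
The perturbed assembly keeps the nominal gains and model inside the
controller/observer but runs the physical plant with perturbed
matrices; the mismatch couples the error block back to the plant block
through `Γ = B + L(D̄ − D)`. At zero perturbation the perturbed
assembly equals the nominal one elementwise (a regression-tested
identity).

## Time stepping

The Grünwald–Letnikov scheme with weights `w_0 = 1`, `w_k = w_{k−1}(1 −
(α+1)/k)` discretizes `D^α`. The default update is semi-implicit —
`(I − dt^α A) x_k = dt^α B u_k − Σ_{j≥1} w_j x_{k−j}` with a single LU
factorization per mode — because the ladder is stiff (`|eig A|` up to
~90 rad^α/s) and the explicit variant (kept for testing) would need
prohibitively small steps. Defaults: `dt = 1 ms`, horizon three breath
periods (11.25 s), full memory. A short-memory truncation is available
for speed; its error concentrates in the slowly decaying (algebraic-
tail) passive-expiration phase and is negligible during the actively
controlled inspiration.

Validation oracles: the scalar relaxation `D^α x = −x + 1` from rest
has the closed form `x(t) = 1 − E_α(−t^α)`; the stepper matches it to
~1×10⁻⁴ relative at `t = 1 s`, `dt = 1 ms` (tolerance asserted: 10⁻³).
At `α = 1` the scheme is backward Euler and converges at first order to
the matrix-exponential solution. Steady sinusoidal amplitudes agree
with the transfer evaluation `C((jω)^α I − A)⁻¹B + D` to <0.1% at 1 Hz.
The Mittag-Leffler reference itself is computed by the log-gamma power
series (reliable for `|z| ≤ 40`) and is cross-checked against
`E_1(z) = e^z` and `E_{1/2}(−x) = erfcx(x)`.

**Breath-cycle switching.** The ventilator switch acts on the plant
input only: during expiration the applied pressure is zero, the plant
empties passively, and the observer is driven by the applied (zero)
input. The reference is a left-closed square wave (a cycle start is
inspiration). What the *integrators* do during expiration is not
determined by the architecture, and the three supported behaviours
differ sharply:

* `freeze` (default) — hold `w1, w2` while the switch is open, release
  at the next inspiration;
* `leak` — let the integrator states decay through `−ε` with the error
  input disconnected;
* `track` — keep integrating `(1+K_r)(0 − y)` against the passive
  outflow.

With an error gain of `1 + K_r = 501` and a slow leak, `track` winds
the integrators up during the 2.5 s expiration and produces a ~800%
flow overshoot at the next breath — incompatible with the smooth
published breath-to-breath traces — so the gated (`freeze`) behaviour
is the default. With it, the mean tracking error during the second
inspiration is ~0.1% and the delivered tidal volume is 598 ml against
the 600 ml target.

## Evaluation metrics

* **Frequency response**: `H(j2πf)` of the reference-to-flow loop on a
  log grid over 0.01–50 Hz (800 points — the model's identified band).
* **Passband**: largest frequency below which `|H|` stays within 3 dB
  of the reference level, interpolated linearly in (log f, dB). The
  reference level is `|H|` at the lowest grid frequency. The loop's DC
  gain proper is zero (the leaky integrators cannot overcome the
  plant's admittance zero at exactly `s = 0`), but the response is flat
  at ≈1 from 0.01 Hz up to the resonant peak (1.54 at ≈3 Hz); the
  plateau convention reads the published "≈6 Hz" figure correctly
  (measured: 5.75 Hz), whereas referencing the peak would report
  4.56 Hz — a statement about the resonance, not the tracking band.
  Both conventions are available (`reference="low_freq" | "peak"`).
* **ITAE**: `∫ t·|v − y| dt`, trapezoidal on the trace grid, `t`
  measured from the horizon start; the default horizon is the first
  breath period, which covers both tracking and passive expiration.
* **Grid search**: all 27 combinations of `r ∈ {100,150,200}`,
  `θ ∈ {5,10,15}°`, `K_r ∈ {100,300,500}` are designed, simulated and
  ranked by ascending ITAE; ties break lexicographically (smaller `r`,
  then `θ`, then `K_r`); infeasible designs are flagged, not dropped.
  An optional passband cap flags designs whose bandwidth exceeds the
  model's identified range. Because synthesis gains are non-unique, the
  ITAE *ranking* is solver-dependent; the grid structure is not.
* **Volumes**: tidal volume integrates flow over one inspiration
  (reference: `0.48 l/s × 1.25 s = 600 ml`); minute volume multiplies
  by the rate (9.6 l/min).
* **Robustness**: each draw multiplies `R_UA` and `C_UA` by independent
  uniform factors on `[1 − p, 1 + p]` (independence is the natural
  reading; the base variates depend only on the seed and draw count, so
  different bands are nested rescalings of the same draws). The
  perturbed closed loop is assembled with nominal gains and every
  eigenvalue classified: inside `S(r, θ)`, inside `F(α)`, or unstable,
  with tolerance 10⁻⁹ on all three tests. Unstable draws are reported,
  never raised. At ±5% some eigenvalues already leave `S(200, 5°)`; at
  ±15% none of 100 draws destabilizes (checked across seeds).

## Problem sizes in the shipped tests

The test suite exercises the full 24-generation model wherever a claim
depends on it (closed-loop spectra, passband, robustness, tracking) and
reduced instances elsewhere: 2–3 stage ladders against a brute-force
Kirchhoff oracle, scalar fractional relaxations against Mittag-Leffler
forms, random matrices ≤6×6 for the LMI/eigenvalue agreement property,
and two-cycle simulations at `dt = 1 ms` (tracking) or coarser steps
(convergence and variant comparisons) to keep the suite fast.

## Known limitations

* The synthesis returns *a* feasible gain, not the analytic center an
  interior-point SDP would give; designed gains track less aggressively
  than the published set unless re-tuned (all performance claims here
  use the published fixture).
* The Grünwald–Letnikov stepper is first-order; waveform-level accuracy
  beyond ~0.1% needs smaller steps or Richardson refinement.
* The robustness study is empirical (sampled), not a formal robust-
  stability certificate; uncertain-model LMI extensions are out of
  scope.
* The model is linear and SISO: no nonlinear hose resistance, patient
  effort, saturation or anti-windup beyond the expiration gating.
* `R_UA`, `C_UA`, `α` are taken as given; identification from
  forced-oscillation data is out of scope.
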