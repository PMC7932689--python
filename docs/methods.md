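# Methods

## The mechanical picture

A fly walking with a tripod gait keeps three legs on the ground at a time.
Collapsing the body to a point mass supported by three massless linear
springs gives the *springy tripod*: a middle leg of length `r` under the
body and a front and hind leg whose footholds sit `±L` from the middle
foothold along the walking direction, all with stiffness `k` and natural
length `R_tri`. In the sagittal plane the body state is `(r, θ)` with `θ`
the angle from vertical (negative before mid-stance; walking direction
+x). The elastic energy is

    V_tri = ½k(R_tri − ℓ₋)² + ½k(R_tri − ℓ₊)² + ½k(R_tri − r)²,
    ℓ∓ = sqrt(r² + L² ∓ 2 r L sinθ).

Expanding `V_tri` to quadratic order about mid-stance (`r = r_m`, `θ = 0`)
yields the **ARSLIP** model — a single effective leg with a radial spring
`k_s`, an angular spring `k_a` and natural length `R`:

    V = ½k_s(R − r)² + ½k_a θ²,

with (matching first and second derivatives at mid-stance; the cross term
vanishes by mirror symmetry)

    k_a = 2 k L² r_m² R_tri / (L² + r_m²)^{3/2}
    k_s = k [3 − 2 L² R_tri / (L² + r_m²)^{3/2}]
    k_s (R − r_m) = k (R_tri − r_m [3 − 2 R_tri / sqrt(L² + r_m²)]).

Geometries with the bracket in `k_s` non-positive (very wide, low tripods
with long natural legs) are outside the expansion's validity and are
rejected, not clamped. The test suite checks the mapping against
independent fourth-order finite differences of `V_tri` (5-point stencils at
`h = 3·10⁻³·scale`; second-order stencils at the float64-optimal `h` still
carry ~10⁻⁵ relative roundoff, too coarse for small `k_a`).

The equations of motion (Euler–Lagrange, polar coordinates about the
foothold) are

    r̈ = r θ̇² + (k_s/m)(R − r) − g cosθ
    θ̈ = −2 θ̇ ṙ / r − k_a θ/(m r²) + (g/r) sinθ,

with SLIP the exact `k_a = 0` case. Nondimensionalization uses body mass
`m`, natural leg length `R` and gravity `g`: `γ_s = k_s R/(mg)`,
`γ_a = k_a/(mgR)`, `Fr = v²/(gR)`, `Ω = θ̇·sqrt(R/g)`, time unit
`sqrt(R/g)`.

## Integration

`solve_ivp` with DOP853, `rtol 1e-10`, `atol 1e-12`, dense output sampled
at the caller's grid; the conserved energy
`E = ½m(ṙ² + r²θ̇²) + ½k_s(R−r)² + ½k_aθ² + mgr cosθ` drifts below 1e-8
relative on every step, which is what fixed the tolerances. Terminal
events at `r ≤ 0.05 R` and `|θ| ≥ π/2` raise a fall error carrying the
failure time (the optimizer explores parameters the animal could not use).
Mid-stance-anchored ("symmetric") runs integrate the past by time
reflection — the state at `−t` is `[r, θ, −ṙ, −θ̇]` of a run started with
reversed rates — valid because the system is autonomous and reversible.
The fitting path relaxes `rtol` to 1e-8 (residual noise ~1e-11 m, far
below data scales) for speed.

## Fly-like vs cockroach-like kinematics

Differentiating `v = ṙ sinθ + rθ̇ cosθ` twice at a mid-stance state with
radial force balance (`k_s(R − r_m) = mg`) gives
`v̈(0) = θ̇ [g − k_a/(m r_m)]`: the horizontal speed has a mid-stance
*maximum* (fly-like) iff `k_a > m g r_m`, a *minimum* (the stiff-SLIP
walking signature, cockroach-like) otherwise. Under the package's
static-balance convention for `R_tri` this predicts a critical per-leg
stiffness `γ_crit(λ) = (1 + λ²)^{3/2}/(2λ²)`, `λ = L/r_m`, with an
interior minimum at `λ = √2` — the regime classifier is nevertheless fully
numerical (simulate, compare `v(Δt)` with `v(0)` at `Δt` = 2% of a quarter
radial period) and the closed form serves only as a test oracle. The
probe is evaluated at exact times (the margin is O(Δt²), ~1e-7 of `v`;
linear interpolation on a coarse grid flips its sign). A corollary worth
noting: with `γ_s = 2` the balanced posture has `r_m/R = ½`, so
`γ_a = 0.5` sits *exactly on* the regime boundary — fly-typical constants
are marginally fly-like, consistent with flies lying just above the curve
near its minimum.

`boundary_curve` brackets and bisects `γ` per geometry (geometric mean
splitting, relative tolerance 1e-3 by default) above the static-support
feasibility limit `γ > 1/(1 + 2 r_m/s)`.

## Gait analysis

Two coordination estimators, both relative to R1:

- **Stance-start delays**: cycle period from consecutive R1 touch-downs;
  each leg contributes its touch-down *nearest* the cycle start (legs may
  lead the reference, so delays are signed), normalized by the period and
  wrapped to (−0.5, 0.5].
- **Phase delays**: instantaneous phases are the analytic-signal angles
  (Hilbert transform) of the swing-interpolated, sliding-mean-detrended
  (window = two median cycle periods) leg positions along the body axis;
  stance runs 0→π, swing −π→0. Per R1 stance the delay is the circular
  mean of `(φ_R1 − φ_leg)/2π` — the sign convention that makes a leg
  *following* R1 report a positive delay, matching the event-based
  estimator.

Delays that straddle the ±0.5 wrap (the opposing tripod) flip sign
stochastically, so summary "medians" are circular: the median of wrapped
residuals about the circular mean, rotated back.

Gait classification is template-based with a configurable tolerance
(±0.125 cycles): *tripod* if the consecutive chain delays R1→L2→R3 and
(L1 at 0.5) L1→R2→L3 are each small — chain rather than absolute delays
because in an M-tripod the rear leg lags the front by the *sum* of two
within-tripod delays; *tetrapod* if the six legs pair into contralateral
pairs at mutual offsets {0, ⅓, ⅔}; otherwise *noncanonical*.

## Step segmentation and descriptors

A step is one tripod stance; its boundaries are midpoints between the
first touch-down of a tripod and the last lift-off of its predecessor, so
windows tile the bout. Per step: half spread `L` (front–hind foothold
distance along the walking direction, halved), effective foothold (their
midpoint), mid-stance time (projected CoM crosses the foothold; fallback
to peak height, flagged), `r_m` (height there), mean/initial speeds,
distance, duration, `Fr`, and detrended height/speed changes. The
walking direction is the principal axis of horizontal CoM displacement, so
the geometry is invariant to rigid rotations of the scene. The detrended
change subtracts the line through the window's endpoint samples and
reports the residual's total excursion `max − min` (a signed sum of the
extremes would cancel to zero for a pure oscillation, contradicting the
strictly positive within-step speed changes the pipeline is meant to
measure). Fitting eligibility: single-support fraction ≥ 0.25 and ≥ 6
eligible steps per fly.

## Per-step fitting

Free parameters: `k_s ∈ (0, 0.05) N/m`, `k_a ∈ [0, 5·10⁻⁸] N·m/rad`
(ARSLIP only), `R` within ±10% of the fly's measured leg length, and the
initial rates within ±10% of their measured values; `r₀, θ₀` are fixed
from the first frame relative to the effective foothold. The objective is
`rmse_z + rmse_x` between the simulated and measured CoM at the frame
times.

Measured rates anchor hard constraints, so their estimation matters more
than usual. A straight-line slope over the first five frames estimates
the rate a couple of frames *in* (the trajectory curves appreciably within
10 ms), so the package differentiates a local quadratic at the first
frame. Under tracking noise the five-frame edge derivative amplifies
noise by ~1/Δt; the per-window noise level is therefore estimated from
robust fourth differences (white noise contributes `√70·σ`, smooth
dynamics only O(d⁴y/dt⁴·Δt⁴), so the two separate cleanly at 380 Hz) and
when it exceeds 6 µm the quadratic window widens to 13 frames, trading a
little curvature bias for much smaller variance.

The "global" search is a seeded multi-start: Latin-hypercube starts over
the *stiffness* dimensions with rates at their measured centers (the rate
boxes are narrow), plus a data-informed center start, each refined by
bounded trust-region least squares with a capped budget; the leading
candidates *and* the center start are then refined tightly (a capped first
pass can leave the true basin ranked behind a shallow decoy — weak-
angular-spring steps amplify initial-condition error like an inverted
pendulum, `e^{λT}`, making the residual valley narrow), and the winner
receives a derivative-free (Powell) polish of the exact summed-RMSE
objective. If every start falls, a deterministic probe grid — dense along
`k_s`, whose survival band can be narrow — hunts for any viable parameter
set before reporting a non-converged, infinite-objective result. Fits are
bit-reproducible under a fixed seed. `fit_both_models` seeds the ARSLIP
search with the SLIP optimum (`k_a = 0`), so the nested-model inequality
`objective(ARSLIP) ≤ objective(SLIP)` holds by construction.

On fly-like steps SLIP frequently cannot even complete the stance within
the measured-rate constraints: without the angular spring the body stalls
before vertical and falls backward (`θ̇₀ < sqrt(g/r)·|θ₀|`), which is the
mechanically transparent form of the model comparison.

## Per-fly geometry prediction

A single `(k, R_tri)` per fly minimizes the summed squared *relative*
errors of the mapped `(k_a, k_s)` against the per-step fitted values
(relative, so that `k_a ~ 10⁻⁸` and `k_s ~ 10⁻²` weigh equally), with
`k ∈ (0, 0.05] N/m`, `R_tri ∈ [0.75, 1.5]·R_real`, seeded multi-start
bounded least squares. The mapped `R` per step is reported as a
diagnostic. Steps with non-finite or non-positive fitted constants are
excluded and logged; at least six usable steps are required.

An information-budget caveat: within a single fly's narrow geometry range
(`L/r_m` ∈ [1, 2], and often less within one bout) the geometry-driven
spread of `γ_s` is ~±10–20%, comparable to the per-step fit uncertainty at
the study's 20 µm tracking noise, so pipeline-level predicted-vs-fitted
correlations on one synthetic bout are weak even when `(k, R_tri)` is
recovered well. The controlled inverse-problem fixtures (exact or ±10%
perturbed mapped constants over the cross-insect geometry range
0.6–2.5) isolate the loop itself and recover correlations above 0.9.

## Synthetic data generator

The generator emulates the tabular output of a 380 Hz recording of one fly
walking straight; its defaults are the study conditions:

| parameter | default | why |
|---|---|---|
| frame rate | 380 Hz | recording rate of the emulated setup |
| vertical noise σ_z | 20 µm | stated vertical tracking resolution |
| horizontal noise σ_x | 20 µm | no separate figure stated; set equal |
| mass, R_real | 1.123 mg, 2.042 mm | measured W1118 morphometrics |
| per-leg k, R_tri | 0.008 N/m, R_real | yields fly-typical γ_s ≈ 2, γ_a ≈ 0.55 at the default geometries |
| speeds | 8–30 mm/s, bounded random walk (20% of range per cycle) | fly walking range; gradual modulation keeps the schedule self-consistent |
| stance duration | 0.75 mm / v | reciprocal law; ~0.75 mm of travel per stance gives fly-typical cycle periods (~0.06–0.12 s) |
| swing duration | 0.03 s − 0.18 s·v[m/s] | the weak linear decrease of the emulated data (−0.00018 s per mm/s) |
| M-tripod deltas | 0.05, 0.05 cycles | small front-leads-middle-leads-rear delays |
| L/r_m law | clip(2.1 − 24·Fr, [1, 2]) | decreasing with Fr and spanning the fly-typical range over the configured speeds |

Per step, the true tripod is `(k, R_tri)` at the law's `L/r_m`, with `r_m`
from mid-stance static balance (linear in `r_m` at fixed `L/r_m`); the CoM
piece is a mid-stance-anchored ARSLIP simulation at the cycle's commanded
speed, sampled at the frame grid, stitched to its neighbors with
*position* continuity only (velocity jumps at boundaries are allowed —
the single-effective-leg model is per-step). Footholds are placed at
`±L` about the effective foothold; leg tracks are body-frame
foothold-minus-CoM in stance with linear return ramps in swing. All
randomness flows from one seed.

What the generator does **not** emulate: double-support mechanics (the
opposing tripod exerts no force during overlap), body pitch/roll and
lateral dynamics, footfall-timing jitter, tracking outliers or
autocorrelated noise, turning and acceleration. Passing tests therefore
show that the pipeline recovers what it assumes — ARSLIP-generated steps
under white Gaussian noise — not that real flies obey ARSLIP.

## Known limitations

- The quadratic expansion ignores cubic terms of the tripod potential
  (relevant for long-hind-legged insects) and per-leg angular/attachment
  forces.
- The fitter's error model is homoscedastic white noise; heavy-tailed
  tracking errors would call for robust losses.
- `γ_a` is weakly identified on short (~12-frame) stance windows at 20 µm
  noise; per-step estimates scatter ~25% there.
- The regime boundary depends (weakly) on the `R_tri` convention and on
  `Fr`; both are exposed as knobs, and the curve tool reports its `Fr`.
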