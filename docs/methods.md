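# Methods

## The compartment model and its solution

The two-tissue compartment model treats brain FDG kinetics as exchange
between arterial plasma (concentration C_p), a free tissue pool C₁ and a
phosphorylated pool C₂:

    dC₁/dt = K₁·C_p − (k₂+k₃)·C₁ + k₄·C₂
    dC₂/dt = k₃·C₁ − k₄·C₂

The tissue response to a unit plasma impulse is bi-exponential,
h(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t), with

    λ_{1,2} = [(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)] / 2
    A₁ = K₁(k₃+k₄−λ₁)/(λ₂−λ₁),   A₂ = K₁(λ₂−k₃−k₄)/(λ₂−λ₁)

so A₁+A₂ = K₁ always. With k₄ = 0 (irreversible trapping) λ₁ is pinned to
exactly zero and the non-decaying amplitude equals K_FDG = K₁k₃/(k₂+k₃) —
the fraction of delivered tracer that is trapped. The repeated-root case
(k₃ = 0 with k₂ = k₄) degenerates to a single exponential because the
second pool is never populated; no t·e^(−λt) term is needed.

The model TAC is computed by convolving h with the plasma curve on a
uniform 1-s grid (the blood counter's native resolution). The convolution
with each exponential term is evaluated exactly for a piecewise-linear
input via a one-pole recursion (y[i+1] = e^(−λΔ)·y[i] + analytic
increment), so the only discretization error is the linear interpolation
of the input itself. Frame values are trapezoidal means of the
instantaneous signal over [start, end]; frame edges must align with the
grid. Agreement with an independent stiff-ODE integration (LSODA,
rtol 1e-10) is at the 1e-8 relative level, far inside the 0.1% the test
suite demands.

Rate constants are stored in the field's units (mL/min/cm³ and min⁻¹) and
converted to per-second — both the decay rates and the amplitudes — at the
convolution boundary.

### Blood-volume blending

The measured signal is modeled as (1−v_b)·tissue + v_b·whole-blood (the
convention of the common commercial kinetic-modeling tools). Some tools
use tissue + v_b·blood instead; `model_tac(..., blend="additive")`
provides that variant for cross-tool comparison. The whole-blood curve
(not plasma) feeds the v_b term.

### Contracts

All inputs are assumed decay-corrected; the package never models physical
decay. Times are seconds, activities kBq/cm³. CMR_glc uses 1 mmol/L =
1 μmol/cm³ and a tissue density of 1 g/cm³ for the per-100-g conversion.

## Input functions

FDG equilibrates slowly into red blood cells, so a whole-blood curve must
be corrected to plasma. Four plasma/blood ratio conventions are built in:
the mouse mono-exponential (0.386·e^(−0.191·t_min) + 1.165, asymptote =
the equilibrium partition coefficient 1.165), a rat bi-exponential
(0.51·e^(−0.1447·t_min) + 0.3·e^(−0.00206·t_min) + 0.8), the constant
1.165, and the identity (whole blood used as IF). Correction and its
inverse are exact pointwise inverses, which the simulator exploits: the
fixture's blood curve is derived from the plasma IF by division.

Constant-rate infusion IFs follow the tri-exponential model

    C_inf(t)  = S·Σ f_x(1 − e^(−r_x t)),                      t ≤ t_i
    C_decr(t) = S·Σ f_x(1 − e^(−r_x t_i))·e^(−r_x (t−t_i)),   t > t_i

with S = A+B+Z the extrapolated steady-state activity and fractional
areas f_a = Aα/(Aα+Bβ+Zζ) etc., which are non-negative and sum to one by
construction. A, B, Z scale with the infusion rate, so an equal-dose
protocol change multiplies the amplitudes by the duration ratio and the
analytic AUC S·t_i is invariant. Rates are per minute.

`fit_triexp` estimates A, B, Z, α, β, ζ with t_i held fixed, in log-space
(positivity by construction) with Levenberg-Marquardt from six starts with
log-spaced rate triples over 0.01–10 min⁻¹; the best loss wins and the
returned components are sorted fast-to-slow. t_i defaults to the argmax of
a 5-s moving average — a deterministic surrogate for reading the curve
maximum by eye. Note that the extrapolated steady state S is weakly
identified from a 45-min record when the slowest rate is ≈0.01 min⁻¹:
single noisy realizations can miss S by ~20% while fitting the observed
span perfectly (the deviant fits have *lower* residuals than the truth),
and only the mean over replicates is accurate to a few percent. Tests
therefore check the Monte-Carlo mean, not single draws.

## Parameter estimation

`fit_2tc` minimizes uniform-weight least squares on frame values with
MINPACK's Levenberg-Marquardt (via lmfit), bounds K₁, k ≤ 5 (guarding
degenerate data), v_b either fixed (default 0.055) or free in [0, 0.2].
Five restarts — defaults K₁=0.2, k₂=0.4, k₃=0.05, k₄=0.01, v_b=0.05,
then ±50% jitter from a fixed seed — make the reported optimum
multistart-robust. Optional frame-duration weighting (√duration) is
available. Pearson's χ² is a *report* metric computed at the optimum, not
the loss: dividing by near-zero model values in early frames would make a
χ² loss undefined. Parameter SDs come from the Jacobian-based covariance.
Non-convergence returns a flagged FitResult, never a silent partial
answer.

## The synthetic scans

The generator reproduces the study conditions end to end with no external
data:

* **Frame schedule** — 45-min scan, 36 contiguous frames: 10-s frames over
  [stop−30 s, stop+60 s] (clipped at zero for the bolus), equal
  10-s-multiple frames before, and a linear duration ramp (20 s up to
  ≤240 s, cumulative-rounded to 10-s multiples) after. This satisfies the
  reconstruction rules (33–39 frames, 10-s minimum bracketing the stop,
  240-s maximum) for all three protocols; the exact layout within those
  constraints is a package choice.
* **Protocol IFs** — the canonical tri-exponential (A, B, Z) =
  (600, 850, 600) kBq/cm³, (α, β, ζ) = (3.0, 0.3, 0.01) min⁻¹, t_i = 300 s,
  peaking near 2000 kBq/cm³, rescaled at equal dose to 10-s bolus and
  900-s infusion. These are synthetic conventions chosen to resemble a
  representative infusion experiment; no published per-scan IF parameters
  exist.
* **Truth parameters** — K₁ = 0.328 mL/min/cm³, k₂ = 0.550, k₃ = 0.079,
  k₄ = 0, v_b = 0.055 (a typical infusion-experiment set). Multi-scan
  studies draw log-normal jitter around these.
* **Noise** — IF samples: additive Gaussian with SD = 32.5 kBq/cm³ + 5% of
  the value (midpoints of the 25–40 kBq/cm³ and 4–6% ranges); TAC frames:
  SD = value·0.8/duration_s. One noisy IF and ten noisy TACs per scan.
  Negative post-noise values are kept — clipping would bias low-activity
  frames upward.
* **Subsampling** — 30/60-s blood sampling is simulated by deleting
  samples between the retained time points; the fit layer interpolates
  linearly onto its 1-s grid.

What the generator does *not* emulate: scanner resolution and
partial-volume effects, scatter/randoms, reconstruction noise correlation
between frames, dispersion and delay in the shunt catheter, and
physiological drift within a scan. Passing tests therefore demonstrate
correctness of the estimation machinery and the *direction* of the
sensitivity effects, not absolute error magnitudes on real scans.

## The studies

Each study is a pure function of (fixture seed, config) returning a tidy
table and a summary; reruns are bit-identical. Conventions: the reference
condition (zero shift, factor 1.0, mouse correction, generating v_b)
normalizes to exactly 1; statistical comparisons use two-tailed t tests —
homoscedastic for independent simulation arms, paired for same-scan
treatment arms — with Bonferroni correction and the number of comparisons
m exposed in the config.

Notable implementation choices:

* **Time shifts** move the IF (and matched blood curve) sample times and
  re-interpolate onto the original grid, holding end values constant
  beyond the support.
* **LOWESS** uses span 0.1 of the record and 2 robustness iterations
  (configurable; no span is canonical). On noise-free *frame* data the
  smoother is near-identity, but on the 1-s IF it flattens the
  infusion-stop corner, which biases K₁ upward by ~5–20% depending on
  span even without noise — data smoothing is genuinely harmful here, not
  merely unhelpful.
* **Frame thinning** ("delete every second point") is realized as zero
  fit-weights on odd frames, since the frame container requires
  contiguity; ceil(n/2) frames inform the fit.
* **Protocol × sampling** fits each of ten noisy TACs against the noisy
  IF subsampled to 1/30/60 s, with the v_b blood curve re-derived from
  the subsampled IF. k₄ is pinned to zero when the truth has k₄ = 0.
* **K₁/k₂ trade-off** scales K₁ by 1.1, searches the scalar k₂ multiplier
  minimizing the summed squared frame differences to the base TAC
  (bounded scalar minimization, tolerance 1e-6), and reports the
  K_FDG-preserving closed form (c·(k₂+k₃)−k₃)/k₂ as an independent
  reference. The objective is extremely flat between those two values —
  that near-degeneracy, and the fact that the residual concentrates
  around the infusion stop and shrinks as the infusion lengthens from
  300 s to 900 s, is precisely the identifiability argument for not
  prolonging the infusion. On the canonical fixture the SSD argmin is
  1.122 on frame TACs (1.116 on the 1-s curve) against the closed form's
  1.114; all are inside the valley where the SSD differs by <10%.

## Numerical choices and degenerate inputs

* Convolution grid 1 s; frame edges must align with it.
* χ² requires strictly positive expected values; fits where the optimal
  model touches zero report χ² = NaN rather than a misleading number.
* v_b grid fits reuse the same multistart policy with 3 starts (the
  constrained problems are well-conditioned).
* An all-zero TAC drives K₁ to the zero bound; a v_b = 1 model returns
  the frame-averaged blood curve exactly.
* Curves shorter than the frame schedule raise a coverage error rather
  than extrapolating silently.

## Known limitations

* Absolute χ² magnitudes depend on the (unknown) weighting of the
  reference commercial tool; only orderings and argmins are meaningful.
* Free-v_b estimates on noisy data are unstable by design of the problem
  (CV above 1 in the replicate studies, versus ~0.04 for K_FDG); the
  package reports them but the default workflow fixes v_b.
* The tri-exponential steady state S is an extrapolation; trust replicate
  means, not single fits.
* The 10-s bolus simulations omit any fast initial distribution phase, so
  bolus-protocol biases at coarse sampling are, if anything,
  underestimated.
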