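# Methods

## Models

**Two-compartment extravascular model.** A dose X₀ with bioavailable
fraction F is absorbed first-order (rate k_a, complete input, no lag time)
into a central compartment (volume V_c) that exchanges with a peripheral
compartment (rates k_12, k_21) and eliminates at k_10. The central
concentration is the triexponential

C(t) = (k_a F X₀ / V_c) · [ c₁ e^(−k_a t) + c₂ e^(−α t) + c₃ e^(−β t) ]

with hybrid constants α ≥ β the roots of x² − (k_12+k_21+k_10)x + k_21k_10 = 0
and coefficients c₁ = (k_21−k_a)/((α−k_a)(β−k_a)) etc. The discriminant
rewrites as (k_12+k_10−k_21)² + 4k_12k_21 ≥ 0, so the roots are always real;
β is computed as (k_21k_10)/α to avoid cancellation. The three coefficients
sum to zero, so C(0) = 0 exactly in reals and to ~10⁻¹³ relative in floats.
The one-compartment Bateman function is the k_12 → 0 limit with k = k_10.

Units are hours and 1/h throughout; concentrations are whatever X₀/V_c
imply (µg/L in the validation study). Nothing is converted implicitly.

**Degenerate parameters.** k_a equal to α, β (or to k within 10⁻⁹ relative
in the one-compartment form), and α = β, make the exponential coefficients
undefined. These raise a typed error rather than being silently perturbed:
such parameter sets never arise in the validation grid, and a perturbation
would corrupt a study without anyone noticing. The only removable
singularity evaluated as a limit is the peak-time expression itself,
(ln a − ln b)/(a − b) → 1/b, which the solver needs near its bracket edge.

## The direct method

From a sampled curve the package extracts:

* **T_max, C_max** — the sample attaining the maximum. Simulated grids are
  near-flat at the peak (adjacent samples can differ by < 0.1%), so ties
  within 10⁻⁶ relative resolve to the *latest* tied time and every profile
  carries a near-tie diagnostic (relative gap to the runner-up). Grid
  near-ties are the dominant uncertainty in the method: a one-step shift of
  T_max on a fast group moves the estimate by tens of percent.
* **the slope series** — forward finite differences of ln C over consecutive
  post-peak intervals. Finite differences, not a smoothing spline, because
  τ and k_max are conventionally read off the sampling grid; a
  central-difference-like alternative is available through the interval
  endpoints kept on the series. Intervals touching a nonpositive
  concentration are dropped (never bridged or imputed — clinical data
  below the quantitation limit carries no slope information).
* **τ, k_max** — the maximizing interval of the series. k_max is the slope
  over the first interval *after* τ, hence τ defaults to the interval's left
  endpoint; a calibration test against all 39 tabulated (τ, k_max) pairs
  confirms the left convention (27 exact matches vs 0 for the right
  endpoint) and the `right` option is kept for sensitivity analysis. A
  series whose maximum sits on the final interval has no interior maximum —
  the one-compartment signature — and raises a typed error directing the
  caller to the classical route with a known removal rate.

The estimate solves T_max = (ln k_a − ln k′)/(k_a − k′) for
k′ = τ·k_max/(τ−T_max). The left side is the reciprocal logarithmic mean of
(k_a, k′), strictly between 1/max and 1/min of the pair; therefore no root
exists with k_a < k′, a root exists on the upper branch iff T_max < 1/k′,
and it is unique. The solver verifies the bracket, runs Newton with the
analytic derivative from k_a⁰ = max(2/T_max, 2k′), falls back to bisection
whenever a step leaves the bracket, and converges at |residual| < 10⁻¹² h
(a unit-test oracle re-finds every root by dense-grid sign change plus plain
bisection). T_max ≥ 1/k′ raises a typed no-admissible-root error — in
practice a flag that feature extraction failed.

## Comparator estimators

**Loo-Riegelman** (needs k_10, k_12, k_21): absorbed fraction
F_abs(t) = [C + k_10·AUC_0t + X_p/V_c] / (k_10·AUC_0∞), with the peripheral
amount propagated by the incremental recursion
X_p(t)/V_c = X_p(t−Δt)/V_c·e^(−k_21Δt) + (k_12/k_21)C(t−Δt)(1−e^(−k_21Δt))
+ k_12·ΔC·Δt/2. The middle term uses the *previous* sample's concentration
(the standard form; the alternative reading "concentration at time zero"
would vanish identically here). k_a is the negative slope of ln(1−F_abs)
against time, regressed from the first positive sample through the last
sample with F_abs ≤ 0.95. The cutoff keeps the regression away from the
F_abs → 1 regime where the reconstructed unabsorbed fraction is pure
accumulated numerical error; AUC_0∞ is the trapezoidal area plus the
exponential tail C_n/k_T.

**Statistical moments**: 1/k_a = MAT = AUMC/AUC − 1/k_T, AUC and AUMC by
linear trapezoid with analytic tails (C_n/k_T and C_n·t_n/k_T + C_n/k_T²).
MAT ≤ 0 raises a typed negative-MAT error, which the study records as NA.

**Terminal rate k_T** (shared by both): log-linear regression with two
window policies. For standalone/clinical use the default is the common
automated lambda-z selection — the best-adjusted-r² suffix of at least 3 of
the last 10 positive samples. The validation study instead uses a fixed
window **[2τ, 3.5τ]**, anchored on the study's own absorption-completion
marker; the rationale is below.

## Model selection

Weighted least squares (weights 1, 1/C, or 1/C², default 1) in
log-parameter space with curve-peeling initialization (terminal regression
→ β; peeled residual → α; 2/T_max → k_a) and a few deterministic
multi-starts; AIC = N·ln(Re) + 2p with N the number of concentration
observations (the standard reading), p = 3 (k_a, k, scale) or 5, and Re
floored at 10⁻¹² so a machine-perfect fit stays finite. Only the AIC
*ordering* between the 1- and 2-compartment fits is meaningful: absolute
magnitudes depend on weighting internals that differ between software
packages, and the fitted "scale" F·X₀/V is a single identifiable lump.

## The validation study

High/medium/low levels for each rate constant are the means of the
descending-sorted thirds of a packaged 36-drug table, rounded to 3 decimals
(the rounding matters: the tightest constraint k_a > k_12 + k_10 holds by
0.002 at the extreme corner). The canonical levels used everywhere are the
study's reported setting values; recomputation from the packaged table
agrees on 11 of 12 values and lands 0.001 high on the top k_a level, whose
source average evidently used unrounded fits. The constrained product
(k_a > k_12 + k_10, k_a > k_12 > k_21, strict) gives exactly 39 groups,
ordered descending — absorption must outrun total removal for a peak to
exist, and distribution into tissue outruns its return.

Each group is simulated noiselessly at 0.1-h steps with X₀ = 2200 µg,
F = 1, V_c = 10 L over a **38-h observation window**, features are
extracted, and all three estimators run (Loo-Riegelman receives the true
micro-constants). Estimator failures become NA cells; nothing aborts the
run. There is no randomness anywhere: the report is byte-reproducible.

**Why a finite window and a τ-anchored terminal regression.** The
comparator methods' characteristic real-world biases exist *only* under
finite sampling. With a quasi-infinite horizon and an oracle terminal
window, k_T → β exactly, and then (i) the moment method's MAT is
*provably negative for every grid group* — MAT → 1/k_a + 1/α − 1/k_21 < 0,
because 1/β overshoots the true disposition residence time
1/α + 1/β − 1/k_21 of a two-compartment drug — so the whole column is NA;
and (ii) Loo-Riegelman becomes essentially exact (it reconstructs
1 − F_abs = e^(−k_a t) up to O(Δt²)), erasing the positive bias that makes
it an interesting comparator. Real studies observe neither regime: their
terminal windows start after absorption ends but well inside the
distribution→elimination transition, giving k_T above β and a meaningfully
truncated AUC tail. The study therefore emulates finite-study conditions:
a 38-h window and a terminal regression over [2τ, 3.5τ]. These two values
were calibrated once, grid-globally, so that the comparator columns land in
the regime of the tabulated reference values (every Loo-Riegelman error
positive; moment errors mostly negative with NA where MAT ≤ 0); they were
then frozen. Per-row comparator values are *not* reproducible in principle
— back-solving the tabulated moment estimates implies terminal rates
scattered between 1.1β and 2.0β with no single window generating them —
which is itself a faithful reproduction of the method's documented
fragility. The direct method's column is insensitive to all of this: its
features live before ~10 h on every group.

What the noiseless generator does **not** emulate: assay noise and LLOQ
censoring, between-subject variability, lag times, sparse clinical sampling
grids, and nonlinear elimination. Passing tests therefore demonstrate
correctness of the estimators and the study machinery, and the *structural*
biases of the comparators under finite observation — not robustness to
measurement error.

## Known limitations

* The direct method inherits the triangle approximation behind k′; its
  error is quantified empirically by the study (median −2.6%, all but the
  peak-near-tie groups within ±30%), not bounded analytically.
* Near-flat peaks and slope maxima on coarse grids shift T_max/τ by a grid
  step; the near-tie diagnostic flags affected profiles (peak gap to the
  runner-up below 0.1%), and flagged rows are exempt from the per-row error
  bound — in practice only the fastest-elimination corner group exceeds it.
* Flip-flop kinetics (k_a below the removal rate) is outside the admissible
  branch by construction and is reported as no-admissible-root, not
  detected as an alternative solution.
* The moment method under an oracle terminal window is structurally
  undefined (negative MAT) for two-compartment drugs; its finite values in
  the study are a property of the window policy, and should be read as
  such.
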