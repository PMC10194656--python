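# kadirect

Estimation of the first-order absorption rate constant (k_a) for drugs whose
disposition follows a **two-compartment model**, using **only extravascular
(oral) concentration–time data** — no intravenous study required.

## The problem

After an oral dose, the classical one-compartment peak-time relation

```
T_max = (ln k_a − ln k) / (k_a − k)
```

lets you solve for k_a when the elimination rate k is known. For
two-compartment drugs the analogous removal rate is k_12 + k_10, but those
micro-constants normally come from intravenous data, which often cannot be
obtained (safety, ethics, formulation). The Loo-Riegelman method has the same
requirement, and the statistical moment method (1/k_a = MRT − 1/k_T) is
notoriously sensitive to the terminal-phase regression.

The **direct method** implemented here replaces k with an apparent removal
rate built from two quantities readable off the oral curve itself. On a
semilog plot, the post-peak decline rate −d ln C/dt of a two-compartment drug
first rises, peaks, then relaxes to the terminal rate β. The peak value is
the **maximum apparent rate constant of disposition, k_max**, and its time
**τ** marks the end of the post-absorption phase (absorption is essentially
complete there). Scaling k_max back over the post-peak window gives

```
k′ = τ · k_max / (τ − T_max)    ≈ k_12 + k_10
```

and k_a is the unique root > k′ of `T_max = (ln k_a − ln k′)/(k_a − k′)`,
found by Newton iteration with a bisection safeguard (the reciprocal
logarithmic mean is strictly monotone on that branch, so the root is unique
whenever T_max < 1/k′).

The package also implements the two comparators (Loo-Riegelman with known
micro-constants; statistical moments with trapezoidal AUC/AUMC and analytic
exponential tails), AIC-based compartment-number judgment by nonlinear least
squares, and a fully deterministic 39-group simulation study that quantifies
each estimator's accuracy across high/medium/low rate-constant levels derived
from 36 literature drugs (shipped as a packaged fixture).

Audience: pharmacokineticists and formulation scientists doing PK evaluation,
bioequivalence work, or IVIVC development for drugs lacking intravenous data.

## Worked example

Simulate the validation study's medium reference group
(k_a = 0.603, k_12 = 0.211, k_21 = 0.176, k_10 = 0.271 h⁻¹, dose 2200 µg,
V_c = 10 L) and estimate k_a from the curve alone:

```console
$ kadirect simulate --ka 0.603 --k12 0.211 --k21 0.176 --k10 0.271 --out demo.csv
$ kadirect estimate-ka demo.csv --method direct
{
  "method": "direct",
  "ka_hat": 0.6839750111363354,
  "k_prime": 0.3524053329252929,
  "tmax": 2.0,
  "tau": 5.0,
  "kmax": 0.21144319975517575,
  "converged": true,
  "iterations": 6
}
```

The peak is at T_max = 2.0 h; the log-slope of the decline peaks at
k_max = 0.211 h⁻¹ at τ = 5.0 h; the implied removal rate is
k′ = 0.352 h⁻¹ (true k_12 + k_10 = 0.482 — the systematic shortfall of the
triangle approximation behind k′); and the solved k_a = 0.684 h⁻¹ is 13%
above the true 0.603 h⁻¹ — typical of the method's accuracy. With the true
micro-constants available, the Loo-Riegelman route on the same curve gives
0.603 h⁻¹ essentially exactly:

```console
$ kadirect estimate-ka demo.csv --method loo-riegelman --k10 0.271 --k12 0.211 --k21 0.176
{
  "method": "loo-riegelman",
  "ka_hat": 0.6027267699588572,
  ...
}
```

The same estimators work on clinical CSV data (`time,concentration`
columns, optional `subject`). The full validation study:

```console
$ kadirect validate-table2 --out report
```

writes `report.csv` (one row per parameter group: true constants, AIC₁/AIC₂,
T_max, τ, k_max, all three estimates with signed relative errors, NA where
the moment method's mean absorption time is negative) and a full-precision
`report.json`. Under the default study conditions the direct method's median
signed relative error is −2.6% with 35/39 groups inside ±20%, Loo-Riegelman
is biased high on every group (median +66% under the finite 38-h observation
window), and the moment method is mostly biased low or undefined — the
direct method wins the median absolute-error comparison without needing
intravenous data. See `docs/methods.md` for exactly what the study does and
does not emulate.

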