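"""Closed-form oral-dosing concentration models.

One- and two-compartment disposition with first-order absorption and
complete input (no lag time). Units are hours and 1/h throughout;
concentrations carry whatever units X0/V imply (µg/L for the validation
study's µg dose and litre volume). Conversions are never done implicitly.

The two-compartment curve is the standard triexponential

    C(t) = ka*F*X0/Vc * [ (k21-ka)/((alpha-ka)(beta-ka)) * e^{-ka t}
                        + (k21-alpha)/((ka-alpha)(beta-alpha)) * e^{-alpha t}
                        + (k21-beta)/((ka-beta)(alpha-beta)) * e^{-beta t} ]

with hybrid constants alpha >= beta the roots of
x^2 - (k12+k21+k10) x + k21*k10 = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateParameterError, ProfileError

#: Relative tolerance under which two rate constants are treated as equal
#: (removable-singularity / degenerate-parameter detection).
RATE_COINCIDENCE_RTOL = 1e-9

__all__ = [
    "PKParams1C",
    "PKParams2C",
    "HybridConstants",
    "ConcProfile",
    "hybrid_constants",
    "conc_1c_oral",
    "conc_2c_oral",
    "tmax_1c",
]


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PKParams1C:
    """One-compartment oral-dosing parameters.

    ka : absorption rate constant (1/h)
    k  : elimination rate constant (1/h)
    V  : apparent volume of distribution (L)
    F  : bioavailable fraction, in (0, 1]
    X0 : dose (mass units)
    """

    ka: float
    k: float
    V: float = 10.0
    F: float = 1.0
    X0: float = 2200.0

    def __post_init__(self) -> None:
        _require_positive(ka=self.ka, k=self.k, V=self.V, X0=self.X0)
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F!r}")


@dataclass(frozen=True)
class PKParams2C:
    """Two-compartment oral-dosing micro-constants and dosing quantities.

    ka  : absorption rate constant (1/h)
    k12 : central -> peripheral transfer rate (1/h)
    k21 : peripheral -> central transfer rate (1/h)
    k10 : elimination rate from the central compartment (1/h)
    Vc  : central-compartment volume (L)
    F   : bioavailable fraction, in (0, 1]
    X0  : dose (mass units)

    Degeneracy (ka equal to alpha or beta, or alpha == beta) is checked at
    evaluation time, not construction time, so parameter sets can be built
    and inspected freely.
    """

    ka: float
    k12: float
    k21: float
    k10: float
    Vc: float = 10.0
    F: float = 1.0
    X0: float = 2200.0

    def __post_init__(self) -> None:
        _require_positive(ka=self.ka, k12=self.k12, k21=self.k21, k10=self.k10,
                          Vc=self.Vc, X0=self.X0)
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F!r}")


@dataclass(frozen=True)
class HybridConstants:
    """Disposition-phase exponential rates: alpha (distribution) >= beta (elimination)."""

    alpha: float
    beta: float


@dataclass(frozen=True)
class ConcProfile:
    """A sampled concentration-time curve.

    times : strictly increasing sampling times (h), first time >= 0
    conc  : nonnegative concentrations, same length as times
    """

    times: np.ndarray
    conc: np.ndarray

    def __init__(self, times, conc) -> None:
        times = np.asarray(times, dtype=float)
        conc = np.asarray(conc, dtype=float)
        if times.ndim != 1 or conc.ndim != 1 or times.shape != conc.shape:
            raise ProfileError("times and conc must be 1-D arrays of equal length")
        if len(times) < 3:
            raise ProfileError(f"a profile needs at least 3 samples, got {len(times)}")
        if times[0] < 0:
            raise ProfileError(f"first sampling time must be >= 0, got {times[0]}")
        if not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ProfileError(f"sampling times must be strictly increasing (row {bad})")
        if np.any(conc < 0):
            bad = int(np.flatnonzero(conc < 0)[0])
            raise ProfileError(f"negative concentration at row {bad}: {conc[bad]}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "conc", conc)
        # freeze the arrays so the dataclass behaves like a value
        times.setflags(write=False)
        conc.setflags(write=False)

    def __len__(self) -> int:
        return len(self.times)


def hybrid_constants(params: PKParams2C) -> HybridConstants:
    """Hybrid (macro) rate constants alpha, beta from the micro-constants.

    Roots of x^2 - (k12+k21+k10) x + k21*k10 = 0.  The discriminant equals
    (k12 + k21 - k10)^2 + ... rearranged as (k12+k21+k10)^2 - 4 k21 k10 =
    (k12 + k10 - k21)^2 + 4 k12 k21 >= 0, so both roots are always real.

    Raises DegenerateParameterError when alpha == beta to within 1e-12
    relative (repeated root; the biexponential form is then undefined).
    """
    s = params.k12 + params.k21 + params.k10
    p = params.k21 * params.k10
    disc = (params.k12 + params.k10 - params.k21) ** 2 + 4.0 * params.k12 * params.k21
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    # computing beta via the product avoids cancellation when alpha >> beta
    beta = p / alpha
    if alpha - beta <= 1e-12 * alpha:
        raise DegenerateParameterError(
            f"repeated disposition root alpha == beta == {alpha:.6g}; "
            "the biexponential disposition form is undefined"
        )
    return HybridConstants(alpha=alpha, beta=beta)


def conc_1c_oral(params: PKParams1C, t):
    """One-compartment oral concentration at time(s) t (h).

    C(t) = ka F X0 / (V (ka-k)) * (e^{-k t} - e^{-ka t}), the Bateman
    function. Raises DegenerateParameterError when |ka-k|/k < 1e-9; the
    l'Hopital limit k F X0 t e^{-k t} / V exists but coincident rates are
    treated as a modelling error rather than silently branched.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    ka, k = params.ka, params.k
    if abs(ka - k) < RATE_COINCIDENCE_RTOL * k:
        raise DegenerateParameterError(
            f"ka ({ka}) coincides with k ({k}); the biexponential form is undefined"
        )
    amp = ka * params.F * params.X0 / (params.V * (ka - k))
    out = amp * (np.exp(-k * t) - np.exp(-ka * t))
    # clip the tiny negative round-off that can appear at t == 0
    return np.maximum(out, 0.0) if out.ndim else float(max(out, 0.0))


def conc_2c_oral(params: PKParams2C, t):
    """Two-compartment oral concentration at time(s) t (h).

    Triexponential in exp(-ka t), exp(-alpha t), exp(-beta t); the three
    coefficients sum to zero so C(0) == 0. Raises DegenerateParameterError
    when ka coincides with alpha or beta within 1e-9 relative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    hyb = hybrid_constants(params)
    ka, k21 = params.ka, params.k21
    alpha, beta = hyb.alpha, hyb.beta
    for name, rate in (("alpha", alpha), ("beta", beta)):
        if abs(ka - rate) < RATE_COINCIDENCE_RTOL * rate:
            raise DegenerateParameterError(
                f"ka ({ka}) coincides with {name} ({rate:.6g}); "
                "the triexponential coefficients are undefined"
            )
    scale = ka * params.F * params.X0 / params.Vc
    c_ka = (k21 - ka) / ((alpha - ka) * (beta - ka))
    c_al = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c_be = (k21 - beta) / ((ka - beta) * (alpha - beta))
    out = scale * (c_ka * np.exp(-ka * t)
                   + c_al * np.exp(-alpha * t)
                   + c_be * np.exp(-beta * t))
    return np.maximum(out, 0.0) if out.ndim else float(max(out, 0.0))


def tmax_1c(ka: float, k: float) -> float:
    """Peak time of the one-compartment oral curve: (ln ka - ln k)/(ka - k).

    Symmetric in its arguments; the removable singularity at ka == k is
    evaluated as the limit 1/k.
    """
    if not (ka > 0 and k > 0):
        raise ValueError(f"rates must be positive, got ka={ka!r}, k={k!r}")
    if abs(ka - k) < RATE_COINCIDENCE_RTOL * k:
        return 1.0 / k
    return (math.log(ka) - math.log(k)) / (ka - k)
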