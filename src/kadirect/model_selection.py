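"""Compartment-number judgment: nonlinear least squares + AIC.

Fits the one- and two-compartment oral models to a sampled profile by
weighted least squares (parameters kept positive through a log
transform, initialized by curve peeling) and scores each fit with

    AIC = N ln(Re) + 2 p,   Re = sum_i W_i (C_i - Chat_i)^2

where N is the number of concentration observations and p the number of
fitted parameters (3 for one compartment: ka, k, scale; 5 for two:
ka, k12, k21, k10, scale; scale = F*X0/V, since F, X0 and V are not
separately identifiable from concentration data alone). Only the AIC
ordering between the two fits is meaningful across software packages —
absolute magnitudes depend on the weighting scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .exceptions import FitError, ProfileError
from .pkmodels import ConcProfile

#: Floor on Re to keep ln(Re) finite on effectively perfect fits.
RE_FLOOR = 1e-12

__all__ = ["FitResult", "aic", "fit_compartment_model"]

_WEIGHT_SCHEMES = ("uniform", "1/C", "1/C2")


@dataclass(frozen=True)
class FitResult:
    """A fitted compartment model: parameter dict, Re, AIC, bookkeeping."""

    params: dict[str, float]
    Re: float
    aic: float
    n_obs: int
    p: int
    converged: bool
    n_compartments: int


def aic(Re: float, n_obs: int, p: int) -> float:
    """N ln(Re) + 2p (natural log). Re must be positive."""
    if not Re > 0:
        raise ValueError(f"Re must be positive, got {Re!r}")
    return n_obs * math.log(Re) + 2 * p


def _weights(conc: np.ndarray, scheme: str) -> np.ndarray:
    if scheme not in _WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; choose from {_WEIGHT_SCHEMES}")
    if scheme == "uniform":
        return np.ones_like(conc)
    floor = max(conc.max() * 1e-6, 1e-300)
    c = np.maximum(conc, floor)
    return 1.0 / c if scheme == "1/C" else 1.0 / c**2


def _model_1c(t: np.ndarray, ka: float, k: float, scale: float) -> np.ndarray:
    if abs(ka - k) < 1e-9 * k:
        k = ka * (1 + 1e-9)
    return scale * ka / (ka - k) * (np.exp(-k * t) - np.exp(-ka * t))


def _model_2c(t: np.ndarray, ka: float, k12: float, k21: float, k10: float,
              scale: float) -> np.ndarray:
    s = k12 + k21 + k10
    disc = max((k12 + k10 - k21) ** 2 + 4 * k12 * k21, 0.0)
    alpha = 0.5 * (s + math.sqrt(disc))
    beta = k21 * k10 / alpha
    # nudge ka off coincidences so the optimizer can traverse them
    for rate in (alpha, beta):
        if abs(ka - rate) < 1e-9 * rate:
            ka = rate * (1 + 1e-8)
    if alpha - beta < 1e-12 * alpha:
        beta = alpha * (1 - 1e-9)
    c_ka = (k21 - ka) / ((alpha - ka) * (beta - ka))
    c_al = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c_be = (k21 - beta) / ((ka - beta) * (alpha - beta))
    return scale * ka * (c_ka * np.exp(-ka * t) + c_al * np.exp(-alpha * t)
                         + c_be * np.exp(-beta * t))


def _peel_terminal(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Terminal slope and intercept from the last third of positive samples."""
    pos = c > 0
    t, c = t[pos], c[pos]
    n = max(3, len(t) // 3)
    res = linregress(t[-n:], np.log(c[-n:]))
    lam = -res.slope if res.slope < 0 else 1.0 / max(t[-1], 1.0)
    return float(lam), float(math.exp(res.intercept))


def _initial_guesses(t, c, n_compartments):
    """Curve-peeling starts: terminal slope -> beta/k; peak time -> ka."""
    lam, coef = _peel_terminal(t, c)
    i_max = int(np.argmax(c))
    tmax = max(float(t[i_max]), float(t[t > 0][0]) if np.any(t > 0) else 1.0)
    ka0 = max(2.0 / tmax, 3.0 * lam)
    cmax = float(c.max())
    if n_compartments == 1:
        scale0 = max(coef, cmax)
        return [
            (ka0, lam, scale0),
            (2 * ka0, lam, scale0),
            (1.5 * lam, 0.8 * lam, scale0),
        ]
    # residual peeling for alpha: subtract the terminal exponential
    resid = c - coef * np.exp(-lam * t)
    mask = (t > t[i_max]) & (resid > 0)
    if mask.sum() >= 3:
        r = linregress(t[mask], np.log(resid[mask]))
        alpha0 = -r.slope if r.slope < 0 else 5 * lam
    else:
        alpha0 = 5 * lam
    alpha0 = max(alpha0, 2.5 * lam)
    guesses = []
    for k21_0 in (2.0 * lam, 0.5 * math.sqrt(alpha0 * lam), 5.0 * lam):
        k10_0 = alpha0 * lam / k21_0
        k12_0 = alpha0 + lam - k21_0 - k10_0
        if k12_0 <= 0:
            k12_0 = 0.1 * alpha0
        guesses.append((ka0, k12_0, k21_0, k10_0, 2.0 * cmax))
    return guesses


def fit_compartment_model(profile: ConcProfile, n_compartments: int,
                          weights: str = "uniform") -> FitResult:
    """Weighted NLS fit of the 1- or 2-compartment oral model.

    Multi-start Levenberg-Marquardt-type optimization (scipy
    ``least_squares``) in log-parameter space; the best converged start
    wins. Raises FitError if no start converges.
    """
    if n_compartments not in (1, 2):
        raise ValueError(f"n_compartments must be 1 or 2, got {n_compartments!r}")
    t, c = profile.times, profile.conc
    p = 3 if n_compartments == 1 else 5
    if int(np.sum(c > 0)) < p + 1:
        raise ProfileError(
            f"need at least {p + 1} positive observations for a "
            f"{n_compartments}-compartment fit"
        )
    w = np.sqrt(_weights(c, weights))
    model = _model_1c if n_compartments == 1 else _model_2c

    def residuals(logx):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = model(t, *np.exp(logx))
        if not np.all(np.isfinite(pred)):
            return np.full_like(c, 1e6)
        return w * (pred - c)

    best = None
    for guess in _initial_guesses(t, c, n_compartments):
        try:
            sol = least_squares(residuals, np.log(np.asarray(guess)),
                                method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=2000 * p)
        except Exception:
            continue
        cost = 2 * sol.cost
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise FitError(f"all {n_compartments}-compartment fit starts failed")
    cost, sol = best
    theta = np.exp(sol.x)
    names = (["ka", "k", "scale"] if n_compartments == 1
             else ["ka", "k12", "k21", "k10", "scale"])
    Re = max(float(cost), RE_FLOOR)
    return FitResult(params=dict(zip(names, map(float, theta))), Re=Re,
                     aic=aic(Re, len(c), p), n_obs=len(c), p=p,
                     converged=bool(sol.success), n_compartments=n_compartments)
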