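"""Comparator ka estimators and the NCA primitives they share.

Two established routes are provided for comparison with the direct method:

* the Loo-Riegelman method, which deconvolves the absorbed fraction from
  the central-compartment concentration using the micro-constants
  (k10, k12, k21) that normally come from an intravenous study; and
* the statistical moment method, which needs no compartmental model at
  all: 1/ka = MAT = AUMC/AUC - 1/kT.

Both are deliberately faithful to common practice (linear trapezoid,
log-linear terminal regression, the incremental peripheral-amount
recursion) rather than to any one vendor's internals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import NegativeMATError, ProfileError, TerminalPhaseError
from .pkmodels import ConcProfile

logger = logging.getLogger(__name__)

__all__ = [
    "LooRiegelmanResult",
    "MomentsResult",
    "auc_trapezoid",
    "terminal_kT",
    "aumc_with_tail",
    "estimate_ka_moments",
    "loo_riegelman_fabs",
    "estimate_ka_loo_riegelman",
]


@dataclass(frozen=True)
class LooRiegelmanResult:
    """Loo-Riegelman output: estimate, absorbed-fraction series, fit quality."""

    ka_hat: float
    fabs: np.ndarray
    intercept_b: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class MomentsResult:
    """Statistical-moment output with every intermediate the method uses."""

    ka_hat: float
    auc_0t: float
    auc_0inf: float
    aumc: float
    mrt: float
    mat: float
    kT: float
    t_half: float
    n_terminal: int


def auc_trapezoid(profile: ConcProfile) -> float:
    """Linear trapezoidal area under the sampled concentration-time curve."""
    return float(np.trapezoid(profile.conc, profile.times))


def terminal_kT(profile: ConcProfile, n_last: int = 10, min_points: int = 3,
                interval: tuple[float, float] | None = None) -> tuple[float, int, float]:
    """Terminal elimination rate from log-linear regression.

    Two window policies:

    * ``interval=None`` (default): among suffixes of the last ``n_last``
      positive-concentration samples (each with at least ``min_points``
      points), pick the one maximizing the adjusted r-squared of ln C on
      t — the usual automated lambda-z selection for clinical data.
    * ``interval=(t0, t1)``: single log-linear regression over all
      positive samples with t0 <= t <= t1 — a fixed window, e.g. anchored
      on the absorption-completion time tau.

    Returns (kT, n_points_used, r_squared). Raises TerminalPhaseError when
    no candidate window yields a positive rate (profile still rising, or
    too few positive samples).
    """
    pos = profile.conc > 0
    if interval is not None:
        t0, t1 = interval
        sel = pos & (profile.times >= t0) & (profile.times <= t1)
        t, c = profile.times[sel], profile.conc[sel]
        if len(t) < min_points:
            raise TerminalPhaseError(
                f"terminal window [{t0:.3g}, {t1:.3g}] h holds {len(t)} positive "
                f"samples; need at least {min_points}"
            )
        res = stats.linregress(t, np.log(c))
        if res.slope >= 0:
            raise TerminalPhaseError("no log-linear decline in the terminal window")
        return float(-res.slope), len(t), float(res.rvalue ** 2)
    t = profile.times[pos][-n_last:]
    c = profile.conc[pos][-n_last:]
    if len(t) < min_points:
        raise TerminalPhaseError(
            f"need at least {min_points} positive terminal samples, got {len(t)}"
        )
    logc = np.log(c)
    best: tuple[float, float, int, float] | None = None  # (adj_r2, kT, n, r2)
    for start in range(0, len(t) - min_points + 1):
        n = len(t) - start
        res = stats.linregress(t[start:], logc[start:])
        if res.slope >= 0:
            continue
        r2 = res.rvalue ** 2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        if best is None or adj > best[0]:
            best = (adj, -res.slope, n, r2)
    if best is None:
        raise TerminalPhaseError("no terminal log-linear decline (profile not falling)")
    _, kT, n, r2 = best
    return float(kT), int(n), float(r2)


def aumc_with_tail(profile: ConcProfile, kT: float) -> float:
    """Area under the first-moment curve with the analytic exponential tail.

    Trapezoid on t*C(t) over the sampled range plus the tail terms
    c_n t_n / kT + c_n / kT**2 for a mono-exponential decline at rate kT
    beyond the last sample.
    """
    if not kT > 0:
        raise ValueError(f"kT must be positive, got {kT!r}")
    t, c = profile.times, profile.conc
    aumc = float(np.trapezoid(t * c, t))
    cn, tn = float(c[-1]), float(t[-1])
    return aumc + cn * tn / kT + cn / kT**2


def estimate_ka_moments(profile: ConcProfile, n_last: int = 10, min_points: int = 3,
                        terminal_interval: tuple[float, float] | None = None
                        ) -> MomentsResult:
    """Statistical moment estimate: ka = 1/MAT = 1/(AUMC/AUC - 1/kT).

    AUC and AUMC are extrapolated beyond the last sample with the
    exponential tail at the terminal rate kT (window policy as in
    ``terminal_kT``). Raises NegativeMATError when MRT <= 1/kT — the
    method then has no admissible rate and studies record the result
    as NA.
    """
    kT, n_terminal, _r2 = terminal_kT(profile, n_last=n_last, min_points=min_points,
                                      interval=terminal_interval)
    auc_0t = auc_trapezoid(profile)
    if auc_0t <= 0:
        raise ProfileError("AUC over the sampled range is not positive")
    cn = float(profile.conc[-1])
    auc_0inf = auc_0t + cn / kT
    aumc = aumc_with_tail(profile, kT)
    mrt = aumc / auc_0inf
    mat = mrt - 1.0 / kT
    if mat <= 0:
        raise NegativeMATError(
            f"MAT = MRT - 1/kT = {mrt:.4g} - {1.0 / kT:.4g} h is nonpositive; "
            "the moment method yields no absorption rate (NA)"
        )
    return MomentsResult(ka_hat=1.0 / mat, auc_0t=auc_0t, auc_0inf=auc_0inf,
                         aumc=aumc, mrt=mrt, mat=mat, kT=kT,
                         t_half=math.log(2.0) / kT, n_terminal=n_terminal)


def loo_riegelman_fabs(profile: ConcProfile, k10: float, k12: float, k21: float,
                       auc_0inf: float) -> np.ndarray:
    """Absorbed fraction at each sampling time by the Loo-Riegelman recursion.

    F_abs(t) = [C(t) + k10*AUC_0t + Xp(t)/Vc] / [k10 * AUC_0inf], with the
    peripheral amount per central volume propagated sample-to-sample:

      Xp(t)/Vc = Xp(t-dt)/Vc * e^{-k21 dt}
                 + (k12/k21) * C(t-dt) * (1 - e^{-k21 dt})
                 + k12 * dC * dt / 2

    (the incremental form with the previous sample's concentration in the
    middle term). The profile must start at t = 0 with C = 0.
    """
    for name, v in (("k10", k10), ("k12", k12), ("k21", k21)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    t, c = profile.times, profile.conc
    # exact-zero up to floating cancellation in the simulated C(0)
    if t[0] != 0 or c[0] > 1e-9 * c.max():
        raise ProfileError("Loo-Riegelman requires a profile starting at t=0 with C=0")
    c = c.copy()
    c[0] = 0.0
    auc_0t = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (c[:-1] + c[1:]))])
    if auc_0inf <= auc_0t[-1]:
        raise ValueError("auc_0inf must exceed the trapezoidal AUC to the last sample")
    xp_vc = np.empty_like(c)
    xp_vc[0] = 0.0
    dt = np.diff(t)
    dc = np.diff(c)
    decay = np.exp(-k21 * dt)
    for i in range(1, len(c)):
        xp_vc[i] = (xp_vc[i - 1] * decay[i - 1]
                    + (k12 / k21) * c[i - 1] * (1.0 - decay[i - 1])
                    + k12 * dc[i - 1] * dt[i - 1] / 2.0)
    return (c + k10 * auc_0t + xp_vc) / (k10 * auc_0inf)


def estimate_ka_loo_riegelman(profile: ConcProfile, k10: float, k12: float,
                              k21: float, fabs_cutoff: float = 0.95,
                              kT_policy: dict | None = None) -> LooRiegelmanResult:
    """Loo-Riegelman ka: -slope of ln(1 - F_abs) against time.

    AUC to infinity is the trapezoidal area plus the exponential tail at
    the terminal rate. The regression window runs from the first positive
    concentration through the last sample with F_abs <= ``fabs_cutoff``;
    points at F_abs >= 1 (possible through numerical error near complete
    absorption) are never usable and the cutoff keeps the regression away
    from that regime.
    """
    if not 0 < fabs_cutoff < 1:
        raise ValueError(f"fabs_cutoff must be in (0, 1), got {fabs_cutoff!r}")
    kT, _, _ = terminal_kT(profile, **(kT_policy or {}))
    auc_0inf = auc_trapezoid(profile) + float(profile.conc[-1]) / kT
    fabs = loo_riegelman_fabs(profile, k10, k12, k21, auc_0inf)
    t = profile.times
    first_pos = int(np.argmax(profile.conc > 0)) if np.any(profile.conc > 0) else len(t)
    usable = np.zeros(len(t), dtype=bool)
    usable[first_pos:] = True
    usable &= (fabs > 0) & (fabs <= fabs_cutoff)
    if int(usable.sum()) < 3:
        raise ProfileError(
            f"need at least 3 samples with 0 < F_abs <= {fabs_cutoff} for the "
            f"absorption regression, got {int(usable.sum())}"
        )
    res = stats.linregress(t[usable], np.log(1.0 - fabs[usable]))
    return LooRiegelmanResult(ka_hat=float(-res.slope), fabs=fabs,
                              intercept_b=float(res.intercept),
                              r_squared=float(res.rvalue ** 2),
                              n_points=int(usable.sum()))
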