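"""Profile feature extraction for the direct method.

From a sampled concentration-time curve this module extracts the direct
method's sufficient statistics: the peak (Tmax, Cmax), the post-peak
log-slope series, and from that series the end of the post-absorption
phase tau together with the maximum apparent disposition rate k_max.

On a two-compartment profile the slope of ln C after the peak first rises
(absorption still feeding the central compartment), peaks at tau where
absorption is essentially complete, then relaxes down to the terminal rate
beta. One-compartment profiles have no such interior maximum — the slope
rises monotonically to the elimination rate — and are rejected with
NoTwoCompartmentSignatureError so the caller can fall back to the
classical peak-time relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import NoTwoCompartmentSignatureError, ProfileError
from .pkmodels import ConcProfile

logger = logging.getLogger(__name__)

#: Relative gap under which two concentrations tie for the maximum.
TMAX_TIE_RTOL = 1e-6

__all__ = [
    "SlopeSeries",
    "ProfileFeatures",
    "find_tmax_cmax",
    "disposition_slopes",
    "locate_kmax",
    "extract_features",
]


@dataclass(frozen=True)
class SlopeSeries:
    """Forward finite-difference slopes of -ln C over post-peak intervals.

    interval_starts[i] is the left endpoint t_i of the interval whose slope
    slopes[i] = (ln C(t_i) - ln C(t_{i+1})) / (t_{i+1} - t_i); interval_ends
    carries the right endpoints for the alternative tau convention.
    """

    interval_starts: np.ndarray
    interval_ends: np.ndarray
    slopes: np.ndarray


@dataclass(frozen=True)
class ProfileFeatures:
    """The direct method's sufficient statistics for one profile.

    tmax / cmax : location and value of the concentration peak
    tau         : end of the post-absorption phase (h), > tmax
    kmax        : maximum apparent disposition rate (1/h)
    tmax_tie_gap: relative gap between the peak and the runner-up sample —
                  a near-tie diagnostic (grid profiles can be flat to <0.1%
                  around the peak, which moves Tmax by one grid step)
    """

    tmax: float
    cmax: float
    tau: float
    kmax: float
    tmax_tie_gap: float = float("nan")


def find_tmax_cmax(profile: ConcProfile) -> tuple[float, float]:
    """Sampling time and value of the maximal concentration.

    Near-ties (samples within 1e-6 relative of the maximum) are resolved to
    the LATEST tied time: simulated grids are flat near the peak and the
    transcendental peak-time relation is consistent with the latest sample
    at which the curve is still effectively at its maximum.
    """
    conc = profile.conc
    cmax = float(conc.max())
    if cmax <= 0:
        raise ProfileError("profile has no positive concentration")
    tied = np.flatnonzero(conc >= cmax * (1.0 - TMAX_TIE_RTOL))
    i = int(tied[-1])
    return float(profile.times[i]), cmax


def tmax_tie_gap(profile: ConcProfile) -> float:
    """Relative gap between the peak concentration and the runner-up sample."""
    conc = profile.conc
    i = int(np.argmax(conc))
    others = np.delete(conc, i)
    if others.size == 0 or conc[i] <= 0:
        return float("nan")
    return float((conc[i] - others.max()) / conc[i])


def disposition_slopes(profile: ConcProfile, tmax: float) -> SlopeSeries:
    """Finite-difference log-slopes over consecutive intervals after tmax.

    Only intervals whose both concentrations are strictly positive are
    kept; dropped intervals are logged. Requires at least 2 usable
    post-peak points (1 interval).
    """
    mask = profile.times > tmax
    t = profile.times[mask]
    c = profile.conc[mask]
    pos = c > 0
    if int(np.sum(pos)) < 2:
        raise ProfileError(
            f"need at least 2 positive post-peak samples for log-slopes, "
            f"got {int(np.sum(pos))}"
        )
    # slopes only over consecutive-sample intervals whose BOTH endpoints are
    # positive; intervals touching a nonpositive sample are dropped, never
    # bridged (no imputation across below-quantitation gaps)
    keep = pos[:-1] & pos[1:]
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning("dropping %d post-peak interval(s) touching nonpositive "
                       "concentrations from the log-slope series", n_dropped)
    logc = np.where(pos, np.log(np.where(pos, c, 1.0)), np.nan)
    slopes = (-np.diff(logc) / np.diff(t))[keep]
    if len(slopes) < 1:
        raise ProfileError("no usable post-peak interval for log-slopes")
    return SlopeSeries(interval_starts=t[:-1][keep], interval_ends=t[1:][keep],
                       slopes=slopes)


def locate_kmax(slopes: SlopeSeries, tau_convention: str = "left") -> tuple[float, float]:
    """(tau, kmax) from the slope series.

    kmax is the maximal interval slope; tau is the start (default) or end
    of the maximizing interval, per ``tau_convention`` ('left'|'right').
    k_max is the apparent disposition rate over the first interval after
    tau, which makes tau the left endpoint of that interval; the right
    endpoint convention is kept for sensitivity checks.

    A series whose maximum sits on the last interval has no interior
    maximum (the slope never turns over, as in one-compartment profiles)
    and raises NoTwoCompartmentSignatureError.
    """
    if tau_convention not in ("left", "right"):
        raise ValueError(f"tau_convention must be 'left' or 'right', got {tau_convention!r}")
    s = slopes.slopes
    if len(s) < 2:
        raise NoTwoCompartmentSignatureError("slope series too short to locate an interior maximum")
    i = int(np.argmax(s))
    smax = s[i]
    # a maximum attained on (or tied with) the final interval means the slope
    # never turned over within the observation window
    if i == len(s) - 1 or s[-1] >= smax * (1.0 - 1e-9):
        raise NoTwoCompartmentSignatureError(
            "post-peak log-slope series is nondecreasing to the end: no "
            "two-compartment signature; use the classical peak-time relation "
            "with a known disposition rate instead"
        )
    kmax = float(s[i])
    tau = float(slopes.interval_starts[i] if tau_convention == "left"
                else slopes.interval_ends[i])
    return tau, kmax


def extract_features(profile: ConcProfile, tau_convention: str = "left") -> ProfileFeatures:
    """Convenience wrapper: peak + slope series + (tau, kmax) in one call."""
    tmax, cmax = find_tmax_cmax(profile)
    series = disposition_slopes(profile, tmax)
    tau, kmax = locate_kmax(series, tau_convention=tau_convention)
    return ProfileFeatures(tmax=tmax, cmax=cmax, tau=tau, kmax=kmax,
                           tmax_tie_gap=tmax_tie_gap(profile))
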