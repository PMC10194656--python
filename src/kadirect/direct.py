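"""The direct method: ka from (Tmax, tau, kmax) alone.

The apparent total removal rate k' = tau * kmax / (tau - Tmax) stands in
for k12 + k10, turning the classical one-compartment peak-time relation

    Tmax = (ln ka - ln k') / (ka - k')

into an equation solvable for ka from extravascular data only. The
left-hand side, the reciprocal logarithmic mean of (ka, k'), is bounded
strictly between 1/max(ka, k') and 1/min(ka, k'); on the admissible branch
ka > k' it decreases strictly from 1/k' (at ka -> k') to 0, so

  * a root exists iff Tmax < 1/k',
  * the root is unique, and
  * no root exists on the ka < k' branch (there the LHS exceeds 1/k' > Tmax).

Newton iteration with the analytic derivative is used, with a bisection
fallback on an expanding bracket if a Newton step leaves the domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import NoAdmissibleRootError

#: Convergence threshold on the residual |g(ka)| (units of hours).
RESIDUAL_TOL = 1e-12
MAX_ITER = 100

__all__ = ["DirectMethodResult", "k_prime", "solve_ka_direct", "solve_ka_classical"]


@dataclass(frozen=True)
class DirectMethodResult:
    """Direct-method output: the estimate plus solver diagnostics."""

    ka_hat: float
    k_prime: float
    iterations: int
    converged: bool
    residual: float


def k_prime(tau: float, kmax: float, tmax: float) -> float:
    """Apparent total removal constant tau*kmax/(tau - Tmax) (1/h).

    Scales the observed k_max back up to the removal rate that was acting
    over the whole post-peak window; estimates k12 + k10.
    """
    if not kmax > 0:
        raise ValueError(f"kmax must be positive, got {kmax!r}")
    if tmax < 0:
        raise ValueError(f"tmax must be nonnegative, got {tmax!r}")
    if tau <= tmax:
        raise ValueError(
            f"tau ({tau}) must exceed tmax ({tmax}): absorption cannot end before the peak"
        )
    return tau * kmax / (tau - tmax)


def _log_mean_recip(ka: float, k: float) -> float:
    """(ln ka - ln k)/(ka - k), with the removable singularity at ka == k -> 1/k."""
    if abs(ka - k) < 1e-12 * k:
        return 1.0 / k
    return (math.log(ka) - math.log(k)) / (ka - k)


def _solve_peak_time(tmax: float, k: float) -> DirectMethodResult:
    """Root ka > k of (ln ka - ln k)/(ka - k) = Tmax via safeguarded Newton."""
    if not k > 0:
        raise ValueError(f"rate must be positive, got {k!r}")
    if not tmax > 0:
        raise ValueError(f"tmax must be positive, got {tmax!r}")
    if tmax >= 1.0 / k:
        raise NoAdmissibleRootError(
            f"Tmax = {tmax:.6g} h >= 1/k' = {1.0 / k:.6g} h: the peak-time "
            "relation has no root with ka > k'; the extracted features are "
            "inconsistent with first-order absorption faster than removal"
        )

    def g(ka: float) -> float:
        return _log_mean_recip(ka, k) - tmax

    def gprime(ka: float) -> float:
        d = ka - k
        if abs(d) < 1e-12 * k:
            # limit of d/dka [(ln ka - ln k)/(ka - k)] at ka == k
            return -0.5 / (k * k)
        return ((ka - k) / ka - (math.log(ka) - math.log(k))) / (d * d)

    # bracket: g > 0 just above k (since tmax < 1/k), g < 0 for large ka
    lo = k * (1.0 + 1e-6)
    hi = max(2.0 / tmax, 2.0 * k)
    n_expand = 0
    while g(hi) > 0:
        hi *= 2.0
        n_expand += 1
        if n_expand > 200:  # pragma: no cover - unreachable for valid input
            raise NoAdmissibleRootError("failed to bracket the peak-time root")
    if g(lo) < 0:
        # root is within a relative 1e-6 of k itself
        return DirectMethodResult(ka_hat=lo, k_prime=k, iterations=0,
                                  converged=True, residual=abs(g(lo)))

    ka = max(2.0 / tmax, 2.0 * k)
    it = 0
    for it in range(1, MAX_ITER + 1):
        res = g(ka)
        if res > 0:
            lo = max(lo, ka)
        elif res < 0:
            hi = min(hi, ka)
        if abs(res) < RESIDUAL_TOL:
            return DirectMethodResult(ka_hat=ka, k_prime=k, iterations=it,
                                      converged=True, residual=abs(res))
        step = res / gprime(ka)
        ka_new = ka - step
        if not (lo < ka_new < hi):
            ka_new = 0.5 * (lo + hi)  # bisection fallback
        ka = ka_new
    res = g(ka)
    return DirectMethodResult(ka_hat=ka, k_prime=k, iterations=it,
                              converged=abs(res) < 1e-8, residual=abs(res))


def solve_ka_direct(tmax: float, tau: float, kmax: float) -> DirectMethodResult:
    """Direct-method ka estimate from profile features only.

    Forms k' = tau*kmax/(tau - Tmax) and solves the peak-time relation for
    the unique root ka > k'. Raises NoAdmissibleRootError when
    Tmax >= 1/k' (no admissible root; flags a feature-extraction failure).
    """
    kp = k_prime(tau, kmax, tmax)
    return _solve_peak_time(tmax, kp)


def solve_ka_classical(tmax: float, k: float) -> float:
    """ka from the classical peak-time relation with a KNOWN removal rate k.

    Supports the one-compartment case (k = elimination rate) and the
    alternative two-compartment route when intravenous data supply
    k = k12 + k10. Same transcendental equation as the direct method, with
    k known rather than inferred from (tau, kmax).
    """
    return _solve_peak_time(tmax, k).ka_hat
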