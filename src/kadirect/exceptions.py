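"""Typed errors raised across the package.

Every estimator failure mode that the validation study must record (rather
than crash on) has its own exception class, so callers can distinguish
"this profile has no two-compartment signature" from genuine bugs.
"""


class KadirectError(Exception):
    """Base class for all package errors."""


class DegenerateParameterError(KadirectError):
    """Parameter set makes a closed-form expression undefined.

    Raised when the absorption rate coincides with a disposition rate
    (ka == k in the one-compartment model, ka == alpha or beta in the
    two-compartment model) or when alpha == beta (repeated disposition
    root), since the multi-exponential concentration formulas then have
    vanishing denominators.
    """


class ProfileError(KadirectError):
    """A concentration-time profile violates its invariants."""


class NoTwoCompartmentSignatureError(KadirectError):
    """The post-peak log-slope series has no interior maximum.

    One-compartment profiles produce a monotonically rising slope series
    that plateaus at the elimination rate; there is then no (tau, k_max)
    pair and the classical Tmax relation should be used instead.
    """


class NoAdmissibleRootError(KadirectError):
    """The transcendental peak-time equation has no root with ka > k'.

    The left-hand side (ln ka - ln k')/(ka - k') is bounded above by 1/k'
    on the ka > k' branch, so Tmax >= 1/k' admits no solution; this almost
    always flags a feature-extraction failure upstream.
    """


class NegativeMATError(KadirectError):
    """Mean absorption time is nonpositive, so 1/MAT is not a rate.

    The statistical moment method reports this as NA: the terminal rate
    constant was large enough that MRT - 1/kT <= 0.
    """


class TerminalPhaseError(KadirectError):
    """No usable log-linear terminal decline in the profile."""


class FitError(KadirectError):
    """Nonlinear least-squares model fit failed to converge."""
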