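"""The 39-group simulation validation study.

High/medium/low levels for each rate constant are derived from a packaged
table of 36 literature immediate-release drugs (descending sort, means of
the top/middle/bottom thirds). Their constrained Cartesian product —
ka > k12 + k10 (drug appears in plasma at all) and ka > k12 > k21
(absorption outruns distribution, central-to-peripheral outruns the
return) — yields exactly 39 parameter groups. Each group is simulated on
a fine grid, features are extracted, all three estimators run, and signed
relative errors against the true ka are tabulated.

The study is fully deterministic: no noise is added anywhere, so the
report is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

from . import model_selection, reference_methods
from .direct import solve_ka_direct
from .exceptions import KadirectError, NegativeMATError
from .features import ProfileFeatures, extract_features
from .pkmodels import ConcProfile, PKParams2C, conc_2c_oral, hybrid_constants

logger = logging.getLogger(__name__)

#: Dosing quantities held fixed across the whole grid (µg, -, L).
DOSE_X0 = 2200.0
DOSE_F = 1.0
DOSE_VC = 10.0

__all__ = [
    "LevelSet", "StudyConfig", "StudyRow", "StudyReport", "SETTING_LEVELS",
    "load_table1", "derive_levels", "build_grid", "relative_error",
    "simulate_group", "run_validation", "absorption_profile",
]


@dataclass(frozen=True)
class LevelSet:
    """High/medium/low setting values (1/h) for each rate constant."""

    ka_levels: tuple[float, float, float]
    k12_levels: tuple[float, float, float]
    k21_levels: tuple[float, float, float]
    k10_levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("ka_levels", "k12_levels", "k21_levels", "k10_levels"):
            triple = getattr(self, name)
            if not (triple[0] > triple[1] > triple[2]):
                raise ValueError(f"{name} must be strictly decreasing, got {triple}")


@dataclass(frozen=True)
class StudyConfig:
    """Everything tunable about the validation run.

    dt              : simulation grid step (h)
    horizon         : observation window end (h). The default, 38 h, is a
                      finite clinical-scale horizon: the comparator
                      estimators' characteristic biases (all-positive
                      Loo-Riegelman errors, mostly-negative moment errors)
                      only exist when a meaningful concentration tail goes
                      unobserved, exactly as in real sampling schedules
    beta_multiples  : optional horizon extension to beta_multiples/beta
                      (None = fixed horizon; extension makes the terminal
                      phase essentially complete for every group)
    tau_convention  : 'left' or 'right' endpoint of the maximizing interval
    fabs_cutoff     : Loo-Riegelman regression window upper bound on F_abs
    kT_window_tau   : (lo, hi) terminal-regression window in multiples of
                      tau — the window starts only after absorption is
                      complete, as a practitioner would place lambda-z on
                      extravascular data; None falls back to the
                      best-adjusted-r2 suffix policy of the last
                      ``kT_n_last`` samples
    kT_n_last       : samples eligible for the suffix terminal policy
    kT_min_points   : minimum points in a terminal regression window
    weights         : residual weighting scheme for the model fits
    run_fits        : compute AIC1/AIC2 per group (the slow part)
    """

    dt: float = 0.1
    horizon: float = 38.0
    beta_multiples: float | None = None
    tau_convention: str = "left"
    fabs_cutoff: float = 0.95
    kT_window_tau: tuple[float, float] | None = (2.0, 3.5)
    kT_n_last: int = 10
    kT_min_points: int = 3
    weights: str = "uniform"
    run_fits: bool = True


@dataclass(frozen=True)
class StudyRow:
    """One grid group: truth, features, three estimates, relative errors.

    Estimates that raised a typed estimator error are None (rendered NA),
    with the reason kept in ``notes``.
    """

    true_params: PKParams2C
    features: ProfileFeatures
    aic1: float | None
    aic2: float | None
    ka_direct: float | None
    ka_lr: float | None
    ka_stm: float | None
    re_direct: float | None
    re_lr: float | None
    re_stm: float | None
    notes: str = ""


@dataclass(frozen=True)
class StudyReport:
    """All rows plus the per-method summary statistics."""

    rows: tuple[StudyRow, ...]
    median_re: dict[str, float]
    mean_abs_re: dict[str, float]
    median_abs_re: dict[str, float]
    na_counts: dict[str, int]
    config: StudyConfig


#: The canonical setting values used throughout the validation. They equal derive_levels() on the packaged table except for
#: the high ka level, where the printed-table mean (1.09858) rounds to 1.099:
#: the study's 1.098 evidently came from averaging unrounded fits. The printed
#: values are kept canonical so the grid matches the validation table exactly.
SETTING_LEVELS = LevelSet(
    ka_levels=(1.098, 0.603, 0.375),
    k12_levels=(0.525, 0.211, 0.133),
    k21_levels=(0.176, 0.067, 0.025),
    k10_levels=(0.571, 0.271, 0.100),
)


def load_table1() -> pd.DataFrame:
    """The packaged 36-drug rate-constant table (columns drug, ka, k12, k21, k10)."""
    with resources.files("kadirect.data").joinpath("table1_rate_constants.csv").open() as fh:
        return pd.read_csv(fh)


def _level_triple(values: np.ndarray) -> tuple[float, float, float]:
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    n = len(v) // 3
    return tuple(round(float(v[i * n:(i + 1) * n].mean()), 3) for i in range(3))


def derive_levels(table1: pd.DataFrame | None = None) -> LevelSet:
    """High/medium/low levels: means of descending-sorted thirds, 3 decimals.

    Rounding to 3 decimals matches the printed setting values and matters:
    the tightest grid constraint (ka > k12 + k10 at the high/high/high
    corner) holds only marginally, so unrounded means would change which
    groups survive.
    """
    if table1 is None:
        table1 = load_table1()
    if len(table1) != 36:
        raise ValueError(f"expected exactly 36 drugs, got {len(table1)}")
    return LevelSet(
        ka_levels=_level_triple(table1["ka"].to_numpy()),
        k12_levels=_level_triple(table1["k12"].to_numpy()),
        k21_levels=_level_triple(table1["k21"].to_numpy()),
        k10_levels=_level_triple(table1["k10"].to_numpy()),
    )


def build_grid(levels: LevelSet) -> list[PKParams2C]:
    """Constrained Cartesian product of the levels, in descending order.

    Keeps combinations with ka > k12 + k10 and ka > k12 > k21 (strict).
    Ordering: descending ka, then k12, then k21, then k10.
    """
    grid = []
    for ka, k12, k21, k10 in product(levels.ka_levels, levels.k12_levels,
                                     levels.k21_levels, levels.k10_levels):
        if ka > k12 + k10 and ka > k12 > k21:
            grid.append(PKParams2C(ka=ka, k12=k12, k21=k21, k10=k10,
                                   Vc=DOSE_VC, F=DOSE_F, X0=DOSE_X0))
    return grid


def relative_error(estimate: float, truth: float) -> float:
    """Signed relative error in percent: (estimate - truth)/truth * 100."""
    if not truth > 0:
        raise ValueError(f"truth must be positive, got {truth!r}")
    return (estimate - truth) / truth * 100.0


def simulate_group(params: PKParams2C, config: StudyConfig = StudyConfig()) -> ConcProfile:
    """Noiseless concentration profile for one group on the study grid.

    The grid runs from 0 at ``dt`` steps to ``horizon`` h, optionally
    extended to ``beta_multiples``/beta for slow-elimination groups.
    """
    end = config.horizon
    if config.beta_multiples is not None:
        beta = hybrid_constants(params).beta
        end = max(end, config.beta_multiples / beta)
    n = int(round(end / config.dt))
    times = np.arange(n + 1) * config.dt
    return ConcProfile(times=times, conc=conc_2c_oral(params, times))


def absorption_profile(ka: float, times) -> np.ndarray:
    """First-order cumulative absorbed fraction 1 - exp(-ka t), in [0, 1)."""
    if not ka > 0:
        raise ValueError(f"ka must be positive, got {ka!r}")
    t = np.asarray(times, dtype=float)
    return 1.0 - np.exp(-ka * t)


def _summaries(rows: list[StudyRow]) -> tuple[dict, dict, dict, dict]:
    median_re, mean_abs, median_abs, na = {}, {}, {}, {}
    for method in ("direct", "lr", "stm"):
        res = [getattr(r, f"re_{method}") for r in rows]
        ok = np.array([x for x in res if x is not None], dtype=float)
        na[method] = sum(1 for x in res if x is None)
        median_re[method] = float(np.median(ok)) if ok.size else float("nan")
        mean_abs[method] = float(np.mean(np.abs(ok))) if ok.size else float("nan")
        median_abs[method] = float(np.median(np.abs(ok))) if ok.size else float("nan")
    return median_re, mean_abs, median_abs, na


def run_validation(levels: LevelSet | None = None,
                   config: StudyConfig = StudyConfig()) -> StudyReport:
    """Simulate every grid group and run all three estimators.

    The Loo-Riegelman estimator receives the TRUE micro-constants (as it
    would from an intravenous study). Typed estimator failures (negative
    MAT, no admissible root, ...) become NA cells, never abort the run.
    """
    if levels is None:
        levels = SETTING_LEVELS
    rows: list[StudyRow] = []
    for params in build_grid(levels):
        profile = simulate_group(params, config)
        features = extract_features(profile, tau_convention=config.tau_convention)
        notes: list[str] = []
        if features.tmax_tie_gap < 1e-3:
            notes.append(f"near-tie at the peak (gap {features.tmax_tie_gap:.1e})")
        interval = None
        if config.kT_window_tau is not None:
            lo, hi = config.kT_window_tau
            interval = (lo * features.tau, hi * features.tau)
        kT_policy = {"n_last": config.kT_n_last, "min_points": config.kT_min_points,
                     "interval": interval}

        ka_direct = ka_lr = ka_stm = None
        try:
            ka_direct = solve_ka_direct(features.tmax, features.tau, features.kmax).ka_hat
        except KadirectError as exc:
            notes.append(f"direct: {exc}")
        try:
            ka_lr = reference_methods.estimate_ka_loo_riegelman(
                profile, k10=params.k10, k12=params.k12, k21=params.k21,
                fabs_cutoff=config.fabs_cutoff, kT_policy=kT_policy).ka_hat
        except KadirectError as exc:
            notes.append(f"loo-riegelman: {exc}")
        try:
            ka_stm = reference_methods.estimate_ka_moments(
                profile, n_last=config.kT_n_last, min_points=config.kT_min_points,
                terminal_interval=interval).ka_hat
        except NegativeMATError:
            notes.append("moments: MAT in negative")
        except KadirectError as exc:
            notes.append(f"moments: {exc}")

        aic1 = aic2 = None
        if config.run_fits:
            try:
                aic1 = model_selection.fit_compartment_model(profile, 1, config.weights).aic
                aic2 = model_selection.fit_compartment_model(profile, 2, config.weights).aic
            except KadirectError as exc:
                notes.append(f"fit: {exc}")

        def _re(est):
            return None if est is None else relative_error(est, params.ka)

        rows.append(StudyRow(true_params=params, features=features,
                             aic1=aic1, aic2=aic2,
                             ka_direct=ka_direct, ka_lr=ka_lr, ka_stm=ka_stm,
                             re_direct=_re(ka_direct), re_lr=_re(ka_lr),
                             re_stm=_re(ka_stm), notes="; ".join(notes)))
    median_re, mean_abs, median_abs, na = _summaries(rows)
    return StudyReport(rows=tuple(rows), median_re=median_re,
                       mean_abs_re=mean_abs, median_abs_re=median_abs,
                       na_counts=na, config=config)
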