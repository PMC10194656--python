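"""Concentration-profile CSV I/O and study-report serialization.

Profiles travel as plain CSV with columns ``time`` (h) and
``concentration`` (any consistent units), plus an optional ``subject``
column; one profile per subject, in input order. Study reports are
written as a human-readable CSV mirroring the validation table (3-decimal
rounding, literal "NA" cells) with a full-precision JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ProfileError
from .pkmodels import ConcProfile
from .study import StudyReport

__all__ = ["read_profiles", "write_profile", "write_report"]

REPORT_COLUMNS = [
    "true_ka", "k12", "k21", "k10", "AIC1", "AIC2", "Tmax", "tau", "kmax",
    "ka_direct", "RE_direct", "ka_lr", "RE_lr", "ka_stm", "RE_stm",
]


def read_profiles(path) -> dict[str, ConcProfile]:
    """Parse profiles from CSV, keyed by subject id (input order preserved).

    Files without a ``subject`` column yield a single profile keyed "".
    Validation failures name the offending row.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("time", "concentration"):
        if required not in cols:
            raise ProfileError(
                f"{path}: missing required column {required!r} "
                f"(found {list(df.columns)})"
            )
    subject_col = cols.get("subject")
    groups = (df.groupby(df[subject_col].astype(str), sort=False)
              if subject_col else [("", df)])
    profiles: dict[str, ConcProfile] = {}
    for subject, sub in groups:
        times = sub[cols["time"]].to_numpy(dtype=float)
        conc = sub[cols["concentration"]].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = sub.index[int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1]
            raise ProfileError(
                f"{path}: non-increasing time at data row {bad + 2} "
                f"(subject {subject!r})"
            )
        try:
            profiles[str(subject)] = ConcProfile(times=times, conc=conc)
        except ProfileError as exc:
            raise ProfileError(f"{path} (subject {subject!r}): {exc}") from exc
    return profiles


def write_profile(profile: ConcProfile, path) -> None:
    """Write a single profile as a two-column CSV."""
    pd.DataFrame({"time": profile.times, "concentration": profile.conc}
                 ).to_csv(path, index=False)


def _row_record(row) -> dict:
    p, f = row.true_params, row.features
    return {
        "true_ka": p.ka, "k12": p.k12, "k21": p.k21, "k10": p.k10,
        "AIC1": row.aic1, "AIC2": row.aic2,
        "Tmax": f.tmax, "tau": f.tau, "kmax": f.kmax,
        "ka_direct": row.ka_direct, "RE_direct": row.re_direct,
        "ka_lr": row.ka_lr, "RE_lr": row.re_lr,
        "ka_stm": row.ka_stm, "RE_stm": row.re_stm,
        "notes": row.notes,
    }


def write_report(report: StudyReport, path) -> tuple[Path, Path]:
    """Write the study report: rounded CSV plus full-precision JSON sidecar.

    Returns the (csv_path, json_path) pair; ``path`` supplies the stem.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")

    records = [_row_record(r) for r in report.rows]
    df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS + ["notes"])
    rounded = df.copy()
    for col in REPORT_COLUMNS:
        rounded[col] = df[col].map(
            lambda x: "NA" if x is None or (isinstance(x, float) and np.isnan(x))
            else f"{x:.3f}")
    rounded.to_csv(csv_path, index=False)

    payload = {
        "config": dataclasses.asdict(report.config),
        "rows": records,
        "summary": {
            "median_re": report.median_re,
            "mean_abs_re": report.mean_abs_re,
            "median_abs_re": report.median_abs_re,
            "na_counts": report.na_counts,
        },
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return csv_path, json_path
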