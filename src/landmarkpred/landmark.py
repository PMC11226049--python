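"""Landmark dataset construction and stacking.

At a landmark time ``ell`` the risk set contains the subjects still
event-free and uncensored (strictly ``T > ell``).  Covariates are
evaluated at ``ell`` by last observation carried forward (a measurement at
exactly ``ell`` is usable).  Residual times are measured from the landmark
and, when requested, administratively truncated at the prediction horizon
``tau``.  Stacking the per-landmark datasets yields the super-dataset on
which the dynamic models are fitted, with the subject id as cluster key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL_COVARIATES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkGrid:
    """Landmark times plus the shared prediction horizon.

    ``time_scale`` is the denominator s of the polynomial time basis
    (1, ell/s, (ell/s)^2); the default of 5 years makes the basis span
    [0, 1] over a five-year landmark period.
    """

    times: np.ndarray
    tau: float
    time_scale: float = 5.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("landmark times must be a non-empty 1-d sequence")
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("landmark times must be strictly increasing")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.time_scale <= 0:
            raise ValueError(f"time_scale must be > 0, got {self.time_scale}")

    def __len__(self) -> int:
        return len(self.times)


def make_landmark_grid(
    start: float, end: float, step: float, tau: float, time_scale: float = 5.0
) -> LandmarkGrid:
    """Evenly spaced landmark times start, start+step, ..., end (inclusive).

    The endpoint is included when it lies on the lattice to within 1e-9.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    n = int(np.floor((end - start) / step + 1e-9))
    times = start + step * np.arange(n + 1)
    return LandmarkGrid(times=times, tau=tau, time_scale=time_scale)


def time_basis(ell: float, time_scale: float = 5.0, degree: int = 2) -> np.ndarray:
    """Polynomial basis (1, ell/s, (ell/s)^2, ...) truncated at ``degree``."""
    if time_scale <= 0:
        raise ValueError(f"time_scale must be > 0, got {time_scale}")
    u = ell / time_scale
    return np.array([u**k for k in range(degree + 1)])


def build_landmark_dataset(
    cohort: Cohort,
    ell: float,
    tau: float,
    truncate: bool = True,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """One landmark dataset: the risk set at ``ell`` with LOCF covariates.

    Returns a frame with ``subject_id``, ``landmark``, the covariate
    columns, the (possibly truncated) ``residual_time``/``residual_event``
    pair, the untruncated ``residual_time_raw``/``residual_event_raw``
    pair, and ``entry``/``exit``/``event_window`` on the study time axis
    for the Cox supermodel.  Subjects at risk but with no measurement at or
    before ``ell`` are excluded (and counted in the log).
    """
    if ell < 0:
        raise ValueError(f"landmark time must be >= 0, got {ell}")
    covariates = list(MODEL_COVARIATES if covariates is None else covariates)

    surv = cohort.survival
    at_risk = surv[surv["time"] > ell].copy()

    time_varying = [c for c in covariates if c in cohort.longitudinal.columns]
    baseline = [c for c in covariates if c not in time_varying]
    missing = [c for c in baseline if c not in surv.columns]
    if missing:
        raise KeyError(
            f"covariates {missing} not found; survival table has "
            f"{sorted(set(surv.columns) - {'subject_id', 'time', 'event'})}, "
            f"longitudinal table has "
            f"{sorted(set(cohort.longitudinal.columns) - {'subject_id', 'time'})}"
        )

    if time_varying:
        meas = cohort.longitudinal[cohort.longitudinal["time"] <= ell]
        locf = meas.sort_values("time").groupby("subject_id").tail(1)
        merged = at_risk.merge(
            locf[["subject_id"] + time_varying], on="subject_id", how="left"
        )
        dropped = int(merged[time_varying[0]].isna().sum())
        if dropped:
            logger.info(
                "landmark %.3g: excluded %d at-risk subject(s) with no measurement at or before the landmark",
                ell,
                dropped,
            )
            merged = merged.dropna(subset=[time_varying[0]])
    else:
        merged = at_risk

    out = merged.reset_index(drop=True)
    out["landmark"] = ell
    out["residual_time_raw"] = out["time"] - ell
    out["residual_event_raw"] = out["event"].astype(int)
    if truncate:
        over = out["residual_time_raw"] > tau
        out["residual_time"] = np.minimum(out["residual_time_raw"], tau)
        out["residual_event"] = np.where(over, 0, out["residual_event_raw"]).astype(int)
    else:
        out["residual_time"] = out["residual_time_raw"]
        out["residual_event"] = out["residual_event_raw"]
    out["entry"] = ell
    out["exit"] = ell + out["residual_time"]
    out["event_window"] = out["residual_event"]
    keep = ["subject_id", "landmark"] + covariates + [
        "residual_time",
        "residual_event",
        "residual_time_raw",
        "residual_event_raw",
        "entry",
        "exit",
        "event_window",
    ]
    return out[keep].sort_values("subject_id", kind="stable").reset_index(drop=True)


def stack_landmark_datasets(
    grid: LandmarkGrid,
    cohort: Cohort,
    truncate: bool = True,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate the landmark datasets over the grid (sorted by ell, id)."""
    parts = []
    for ell in grid.times:
        part = build_landmark_dataset(cohort, ell, grid.tau, truncate=truncate, covariates=covariates)
        if part.empty:
            logger.warning("empty risk set at landmark %.3g", ell)
            continue
        parts.append(part)
    if not parts:
        cols = build_landmark_dataset(cohort, grid.times[0], grid.tau, covariates=covariates).columns
        return pd.DataFrame(columns=cols)
    stacked = pd.concat(parts, ignore_index=True)
    return stacked.sort_values(["landmark", "subject_id"], kind="stable").reset_index(drop=True)


def expand_design(
    stacked: pd.DataFrame,
    covariates: list[str],
    degree: int = 2,
    time_scale: float = 5.0,
    intercept: bool = True,
    intercept_interaction: bool = False,
) -> pd.DataFrame:
    """Design matrix with covariate x time-basis interaction columns.

    Column order: the intercept block first (a single constant column
    unless ``intercept_interaction``), then for each covariate p the
    products X_p * (ell/s)^k for k = 0..degree, named ``p``, ``p:t``,
    ``p:t2``, ... with t = ell / time_scale.
    """
    missing = [c for c in covariates if c not in stacked.columns]
    if missing:
        raise KeyError(
            f"covariates {missing} not in stacked data; available: "
            f"{sorted(stacked.columns)}"
        )
    u = stacked["landmark"].to_numpy(float) / time_scale
    cols: dict[str, np.ndarray] = {}
    if intercept:
        cols["Intercept"] = np.ones(len(stacked))
        if intercept_interaction:
            for k in range(1, degree + 1):
                cols[f"Intercept:t{k if k > 1 else ''}"] = u**k
    for c in covariates:
        x = stacked[c].to_numpy(float)
        cols[c] = x
        for k in range(1, degree + 1):
            cols[f"{c}:t{k if k > 1 else ''}"] = x * u**k
    return pd.DataFrame(cols, index=stacked.index)
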