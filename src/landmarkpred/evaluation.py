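"""Held-out assessment: concordance (AUC) and IPCW Brier-type scores.

All metrics are computed per landmark on the held-out landmark risk set,
never pooled across landmarks.  Discrimination uses the pairwise
concordance of risk scores (higher score = worse prognosis); because the
models emit survival-type predictions (conditional RMST or survival
probability), the evaluator negates them before scoring.  Calibration
uses the inverse-probability-of-censoring-weighted Brier score for
probability-type predictions and its squared-error analogue (in years
squared, with no upper bound of 1) for RMST-type predictions.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort
from .landmark import LandmarkGrid, build_landmark_dataset
from .pseudo import StepSurvival, censoring_km

logger = logging.getLogger(__name__)


def split_train_test(cohort: Cohort, fraction: float = 0.75, seed: int = 0):
    """Subject-level train/test partition (train size = round(n * fraction))."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ids = cohort.survival["subject_id"].to_numpy()
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    return cohort.subset(perm[:n_train]), cohort.subset(perm[n_train:])


def auc_concordance(risk_scores, times, events, ties: str = "strict") -> float:
    """Pairwise concordance of risk scores among usable pairs.

    A pair (j, i) is usable when T_j < T_i and subject j had the event;
    it is concordant when the earlier failure carries the higher risk
    score.  With ``ties="strict"`` tied scores contribute nothing (the
    printed-formula reading); ``ties="half"`` gives them half credit.
    Returns NaN (with a warning) when no usable pair exists.
    """
    eta = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    usable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    denom = usable.sum()
    if denom == 0:
        warnings.warn("no usable pairs for concordance; returning NaN")
        return float("nan")
    conc = usable & (eta[:, None] > eta[None, :])
    num = float(conc.sum())
    if ties == "half":
        num += 0.5 * float((usable & (eta[:, None] == eta[None, :])).sum())
    elif ties != "strict":
        raise ValueError(f"ties must be 'strict' or 'half', got {ties!r}")
    return num / float(denom)


def _check_weights(G: StepSurvival, where: np.ndarray, label: str) -> None:
    if np.any(where <= 0):
        raise ValueError(
            f"censoring survival estimate is 0 at a needed {label}; "
            "use a smaller evaluation time or truncate the window"
        )


def brier_ipcw_prob(predictions, times, events, t: float, G: StepSurvival) -> float:
    """IPCW Brier score for survival-probability predictions at time t.

    Observed failures before t are weighted by 1/G(T-), survivors past t
    by 1/G(t); subjects censored before t contribute zero.  With no
    censoring (G = 1) this is the classical Brier score.
    """
    p = np.asarray(predictions, dtype=float)
    T = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability predictions must lie in [0, 1]")
    died = (T <= t) & (d == 1)
    alive = T > t
    g_tm = G.survival_at(T[died], left=True)
    _check_weights(G, g_tm, "failure time")
    g_t = G.survival_at(t)
    if alive.any():
        _check_weights(G, np.asarray([g_t]), "evaluation time")
    total = np.sum((0.0 - p[died]) ** 2 / g_tm)
    total += np.sum((1.0 - p[alive]) ** 2 / g_t)
    return float(total / len(p))


def brier_ipcw_rmst(predictions, times, events, t: float, G: StepSurvival) -> float:
    """IPCW squared-error score for RMST-type predictions (years^2).

    Failures contribute (T_i - mu_i)^2 / G(T-); survivors past t
    contribute (t - mu_i)^2 / G(t).  Unlike the probability version this
    score has no upper bound of 1.
    """
    mu = np.asarray(predictions, dtype=float)
    T = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    died = (T <= t) & (d == 1)
    alive = T > t
    g_tm = G.survival_at(T[died], left=True)
    _check_weights(G, g_tm, "failure time")
    g_t = G.survival_at(t)
    if alive.any():
        _check_weights(G, np.asarray([g_t]), "evaluation time")
    total = np.sum((T[died] - mu[died]) ** 2 / g_tm)
    total += np.sum((t - mu[alive]) ** 2 / g_t)
    return float(total / len(mu))


def evaluate_over_landmarks(
    models: dict,
    test_cohort: Cohort,
    grid: LandmarkGrid,
    covariates: list[str],
    ties: str = "strict",
) -> pd.DataFrame:
    """Per-landmark AUC and calibration for each fitted model variant.

    ``models`` maps a display name to a fitted dynamic model or
    :class:`~landmarkpred.models.StaticModelSet`.  Returns one row per
    (model, landmark) with the at-risk and in-window event counts.
    """
    rows = []
    for ell in grid.times:
        ell = float(ell)
        test = build_landmark_dataset(test_cohort, ell, grid.tau, truncate=True, covariates=covariates)
        baseline_test = None
        for name, model in models.items():
            family = model.family
            source = getattr(model, "covariate_source", "current")
            if test.empty:
                logger.warning("empty test risk set at landmark %.3g", ell)
                rows.append((name, family, ell, np.nan, np.nan, 0, 0))
                continue
            frame = test
            if source == "baseline":
                if baseline_test is None:
                    base_vals = build_landmark_dataset(test_cohort, 0.0, grid.tau, covariates=covariates)
                    baseline_test = test.drop(columns=covariates).merge(
                        base_vals[["subject_id"] + covariates], on="subject_id", how="inner"
                    )
                frame = baseline_test
            try:
                pred = model.predict(frame[covariates], ell)
            except KeyError:
                logger.warning("%s has no fitted model at landmark %.3g", name, ell)
                rows.append((name, family, ell, np.nan, np.nan, len(frame), 0))
                continue
            t_res = frame["residual_time"].to_numpy(float)
            d_res = frame["residual_event"].to_numpy(int)
            auc = auc_concordance(-pred, t_res, d_res, ties=ties)
            G = censoring_km(frame["residual_time_raw"].to_numpy(float), frame["residual_event_raw"].to_numpy(int))
            t_raw = frame["residual_time_raw"].to_numpy(float)
            d_raw = frame["residual_event_raw"].to_numpy(int)
            if family == "PM":
                brier = brier_ipcw_rmst(pred, t_raw, d_raw, grid.tau, G)
            else:
                brier = brier_ipcw_prob(pred, t_raw, d_raw, grid.tau, G)
            rows.append((name, family, ell, auc, brier, len(frame), int(d_res.sum())))
    return pd.DataFrame(
        rows,
        columns=["model", "family", "landmark", "auc", "brier", "n_at_risk", "n_events_window"],
    )
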