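"""Dynamic landmark supermodels and their static comparators.

Three families share the stacked-landmark design with quadratic
time-interaction terms:

* ``PM`` — pseudo-mean (conditional RMST) outcomes in a GEE with
  independence working correlation and, by default, the identity link;
* ``PP`` — pseudo survival probabilities, same estimating equations;
* ``cox`` — a Cox proportional-hazards supermodel on the study time axis
  with delayed entry at each landmark and administrative censoring at
  ``ell + tau``, with a single Breslow-type baseline cumulative hazard.

Because every subject contributes a row to each landmark dataset it
survives, all variances are robust sandwich estimates clustered by
subject.  The static comparators are:

* SM1 — per-landmark refits using the covariate values frozen at t = 0;
* SM2 — a single baseline (ell = 0) fit whose predictions are evaluated
  with the covariates observed at the landmark;
* SM3 — per-landmark refits on the covariates observed at the landmark.

None of the static designs carries time-interaction terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from statsmodels.genmod.cov_struct import Independence
from statsmodels.genmod.families import Gaussian, links
from statsmodels.genmod.generalized_estimating_equations import GEE

from .cohort import Cohort
from .landmark import LandmarkGrid, build_landmark_dataset, expand_design, time_basis
from .pseudo import attach_pseudo_outcomes

logger = logging.getLogger(__name__)

_LINKS = {
    "identity": links.Identity,
    "log": links.Log,
    "logit": links.Logit,
    "cloglog": links.CLogLog,
}


@dataclass(frozen=True)
class DynamicCoefficient:
    """The covariate effect beta_p(ell) with its 95% confidence interval."""

    covariate: str
    ell: float
    value: float
    se: float
    ci_low: float
    ci_high: float


def evaluate_dynamic_coefficient(
    coefficients, ell: float, time_scale: float = 5.0
) -> float:
    """Polynomial-in-time effect b0 + b1*(ell/s) + b2*(ell/s)^2 + ...

    ``coefficients`` are the constant, linear, quadratic, ... terms of one
    covariate's time interaction.
    """
    c = np.asarray(coefficients, dtype=float)
    basis = time_basis(ell, time_scale=time_scale, degree=len(c) - 1)
    return float(basis @ c)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(
            f"design matrix is rank deficient ({rank}/{X.shape[1]}); "
            f"collinear or degenerate columns: {bad or 'unidentified'}"
        )


@dataclass
class FittedSupermodel:
    """A fitted landmark model: coefficients, clustered covariance, basis."""

    family: str  # "PM" | "PP" | "cox"
    covariates: list[str]
    degree: int
    time_scale: float
    tau: float
    link: str
    params: pd.Series
    cov: pd.DataFrame
    baseline_cumhaz: pd.Series | None = None  # Cox only: Lambda_0 on its time axis
    baseline_axis: str = "study"  # "study" (supermodel) or "residual" (per-landmark)
    grid_range: tuple[float, float] = (0.0, 5.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = self.cov.to_numpy(float)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("covariance matrix is not positive semi-definite")

    # ---- coefficients -------------------------------------------------
    def _term_names(self, covariate: str) -> list[str]:
        return [covariate] + [f"{covariate}:t{k if k > 1 else ''}" for k in range(1, self.degree + 1)]

    def coefficient_terms(self, covariate: str) -> np.ndarray:
        """(constant, linear, quadratic, ...) interaction terms for one covariate."""
        if covariate not in self.covariates:
            raise KeyError(f"{covariate!r} not among fitted covariates {self.covariates}")
        return self.params.reindex(self._term_names(covariate)).fillna(0.0).to_numpy()

    def dynamic_coefficient(self, covariate: str, ell: float) -> DynamicCoefficient:
        """beta_p(ell) with a delta-method 95% CI from the clustered covariance."""
        terms = self.coefficient_terms(covariate)
        basis = time_basis(ell, time_scale=self.time_scale, degree=self.degree)
        names = [n for n in self._term_names(covariate) if n in self.params.index]
        b = basis[: len(names)]
        sigma = self.cov.loc[names, names].to_numpy(float)
        value = float(basis @ terms)
        se = float(np.sqrt(b @ sigma @ b))
        return DynamicCoefficient(
            covariate, ell, value, se, value - 1.96 * se, value + 1.96 * se
        )

    # ---- prediction ---------------------------------------------------
    def _design_row(self, X: pd.DataFrame, ell: float) -> np.ndarray:
        frame = X.copy()
        frame["landmark"] = ell
        D = expand_design(
            frame,
            self.covariates,
            degree=self.degree,
            time_scale=self.time_scale,
            intercept=self.family in ("PM", "PP"),
        )
        return D.reindex(columns=self.params.index, fill_value=0.0).to_numpy(float)

    def _cumhaz_at(self, t) -> np.ndarray:
        ch = self.baseline_cumhaz
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(ch.index.to_numpy(float), t, side="right") - 1
        vals = np.where(idx < 0, 0.0, ch.to_numpy()[np.clip(idx, 0, None)])
        return vals

    def predict(self, X: pd.DataFrame, ell: float) -> np.ndarray:
        """Conditional prediction at horizon tau given survival to ell.

        PM: conditional RMST in years, clipped to [0, tau].  PP: survival
        probability, clipped to [0, 1].  Cox: exp(-DeltaLambda_0 * exp(lp)).
        """
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise KeyError(f"prediction input lacks covariates {missing}")
        D = self._design_row(X, ell)
        lp = D @ self.params.to_numpy(float)
        if self.family == "cox":
            if self.baseline_axis == "study":
                delta = self._cumhaz_at(ell + self.tau) - self._cumhaz_at(ell)
            else:
                delta = self._cumhaz_at(self.tau)
            return np.clip(np.exp(-delta * np.exp(lp)), 0.0, 1.0)
        inv = _LINKS[self.link]().inverse
        pred = inv(lp)
        hi = self.tau if self.family == "PM" else 1.0
        n_clip = int(np.sum((pred < 0) | (pred > hi)))
        if n_clip:
            logger.info("%s prediction: clipped %d value(s) to [0, %g]", self.family, n_clip, hi)
        return np.clip(pred, 0.0, hi)


def fit_gee_supermodel(
    stacked: pd.DataFrame,
    covariates: list[str],
    tau: float,
    degree: int = 2,
    time_scale: float = 5.0,
    family: str = "PM",
    link: str = "identity",
) -> FittedSupermodel:
    """Fit the pseudo-outcome supermodel by GEE.

    Requires a ``pseudo`` column (see
    :func:`landmarkpred.pseudo.attach_pseudo_outcomes`).  Independence
    working correlation with clusters = subject, so under the identity
    link the point estimates coincide with least squares and the reported
    covariance is the robust sandwich.
    """
    if "pseudo" not in stacked.columns:
        raise ValueError("stacked data has no 'pseudo' column; attach pseudo-outcomes first")
    if family not in ("PM", "PP"):
        raise ValueError(f"family must be 'PM' or 'PP', got {family!r}")
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(_LINKS)}")
    X = expand_design(stacked, covariates, degree=degree, time_scale=time_scale, intercept=True)
    _check_full_rank(X)
    model = GEE(
        stacked["pseudo"].to_numpy(float),
        X,
        groups=stacked["subject_id"].to_numpy(),
        family=Gaussian(link=_LINKS[link]()),
        cov_struct=Independence(),
    )
    res = model.fit()
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"GEE failed to converge: {res.params}")
    return FittedSupermodel(
        family=family,
        covariates=list(covariates),
        degree=degree,
        time_scale=time_scale,
        tau=tau,
        link=link,
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        grid_range=(float(stacked["landmark"].min()), float(stacked["landmark"].max())),
        meta={"n_rows": len(stacked), "n_subjects": stacked["subject_id"].nunique()},
    )


def fit_cox_supermodel(
    stacked: pd.DataFrame,
    covariates: list[str],
    tau: float,
    degree: int = 2,
    time_scale: float = 5.0,
) -> FittedSupermodel:
    """Fit the stacked Cox supermodel by maximum partial likelihood.

    Rows enter on the study time axis with delayed entry at their landmark
    and administrative censoring at ``ell + tau``; the variance is the
    clustered (by subject) robust sandwich and the Breslow-type baseline
    cumulative hazard is stored for conditional survival prediction.
    """
    if stacked["event_window"].sum() == 0:
        raise ValueError("no events inside the prediction windows; Cox fit undefined")
    X = expand_design(stacked, covariates, degree=degree, time_scale=time_scale, intercept=False)
    _check_full_rank(X)
    df = X.copy()
    df["entry"] = stacked["entry"].to_numpy(float)
    df["exit"] = stacked["exit"].to_numpy(float)
    df["event_window"] = stacked["event_window"].to_numpy(int)
    df["subject_id"] = stacked["subject_id"].to_numpy()
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="exit",
        event_col="event_window",
        entry_col="entry",
        cluster_col="subject_id",
        robust=True,
        # tight Newton tolerances: the default stopping rule can leave the
        # last ~1e-5 step unapplied, which matters for oracle comparisons
        fit_options={"precision": 5e-14, "r_precision": 1e-15},
    )
    # baseline hazard at the zero covariate vector via the public API
    zero = pd.DataFrame({c: [0.0] for c in X.columns})
    cumhaz = cph.predict_cumulative_hazard(zero)
    baseline = pd.Series(cumhaz.iloc[:, 0].to_numpy(), index=cumhaz.index.to_numpy(float))
    return FittedSupermodel(
        family="cox",
        covariates=list(covariates),
        degree=degree,
        time_scale=time_scale,
        tau=tau,
        link="log",
        params=pd.Series(cph.params_.to_numpy(), index=X.columns),
        cov=pd.DataFrame(
            cph.variance_matrix_.to_numpy(), index=X.columns, columns=X.columns
        ),
        baseline_cumhaz=baseline,
        baseline_axis="study",
        grid_range=(float(stacked["landmark"].min()), float(stacked["landmark"].max())),
        meta={"n_rows": len(stacked), "n_subjects": stacked["subject_id"].nunique()},
    )


def coefficient_table(model: FittedSupermodel) -> pd.DataFrame:
    """Term-level summary (estimate, robust SE, z, p) mirroring a report table."""
    from scipy import stats

    se = np.sqrt(np.diag(model.cov.to_numpy(float)))
    z = model.params.to_numpy() / np.where(se > 0, se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": model.params.index, "estimate": model.params.to_numpy(), "se": se, "p_value": p}
    )


# ---------------------------------------------------------------------------
# static comparators
# ---------------------------------------------------------------------------


@dataclass
class StaticModelSet:
    """SM1/SM2/SM3 comparators with a prediction interface matching the dynamic model.

    ``covariate_source`` tells the evaluator whether predictions consume
    the covariates observed at the landmark ("current") or the values
    frozen at study entry ("baseline").
    """

    variant: str  # "SM1" | "SM2" | "SM3"
    family: str
    models: dict  # ell -> FittedSupermodel, or {"pooled": FittedSupermodel}
    covariate_source: str  # "baseline" | "current"
    tau: float

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model_for(self, ell: float) -> FittedSupermodel:
        if "pooled" in self.models:
            return self.models["pooled"]
        key = min(self.models, key=lambda l: abs(l - ell))
        if abs(key - ell) > 1e-6:
            raise KeyError(f"no static model fitted at landmark {ell}")
        return self.models[key]

    def predict(self, X: pd.DataFrame, ell: float) -> np.ndarray:
        m = self.model_for(ell)
        if m.family == "cox" and m.baseline_axis == "study" and "pooled" in self.models:
            return m.predict(X, ell)  # conditional via Lambda0(ell+tau) - Lambda0(ell)
        return m.predict(X, 0.0)  # per-landmark fits live on the residual scale


def _fit_single(
    landmark_data: pd.DataFrame,
    covariates: list[str],
    tau: float,
    family: str,
    link: str,
) -> FittedSupermodel:
    """One static (no time interaction) fit on a single landmark dataset."""
    data = landmark_data.copy()
    data["landmark"] = 0.0  # static design: basis degree 0, residual scale
    if family in ("PM", "PP"):
        data = attach_pseudo_outcomes(data, tau, kind="mean" if family == "PM" else "prob")
        return fit_gee_supermodel(data, covariates, tau, degree=0, family=family, link=link)
    data["entry"] = 0.0
    data["exit"] = data["residual_time"]
    m = fit_cox_supermodel(data, covariates, tau, degree=0)
    m.baseline_axis = "residual"
    return m


def fit_static_model(
    variant: str,
    family: str,
    cohort: Cohort,
    grid: LandmarkGrid,
    covariates: list[str],
    link: str = "identity",
) -> StaticModelSet:
    """Fit one of the static comparators SM1, SM2 or SM3."""
    if variant not in ("SM1", "SM2", "SM3"):
        raise ValueError(f"variant must be SM1, SM2 or SM3, got {variant!r}")
    tau = grid.tau
    if variant == "SM2":
        base = build_landmark_dataset(cohort, 0.0, tau, truncate=family != "cox", covariates=covariates)
        if family == "cox":
            # full-follow-up baseline Cox: its cumulative hazard extends past
            # tau, so later-landmark predictions stay conditional
            base["entry"] = 0.0
            base["exit"] = base["residual_time"]
            base["event_window"] = base["residual_event"]
            base["landmark"] = 0.0
            m = fit_cox_supermodel(base, covariates, tau, degree=0)
        else:
            m = _fit_single(base, covariates, tau, family, link)
        return StaticModelSet(variant, family, {"pooled": m}, "current", tau)

    source = "baseline" if variant == "SM1" else "current"
    models: dict[float, FittedSupermodel] = {}
    baseline_values = None
    if variant == "SM1":
        baseline_values = build_landmark_dataset(cohort, 0.0, tau, covariates=covariates)[
            ["subject_id"] + covariates
        ]
    for ell in grid.times:
        data = build_landmark_dataset(cohort, float(ell), tau, truncate=True, covariates=covariates)
        if data.empty:
            logger.warning("%s: empty risk set at landmark %.3g, skipped", variant, ell)
            continue
        if variant == "SM1":
            data = data.drop(columns=covariates).merge(baseline_values, on="subject_id", how="inner")
        try:
            models[float(ell)] = _fit_single(data, covariates, tau, family, link)
        except ValueError as exc:
            # small late-landmark risk sets can lose all variation in a rare
            # covariate; skip the landmark rather than abort the comparator
            logger.warning("%s: landmark %.3g skipped (%s)", variant, ell, exc)
    return StaticModelSet(variant, family, models, source, tau)
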