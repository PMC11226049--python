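"""Synthetic cirrhosis-style cohort generator with a known ground-truth hazard.

The generator produces the two tables the rest of the pipeline consumes:

* a survival table — one row per subject with baseline covariates
  (``age`` in years; ``sex``, ``etoh``, ``biliary``, ``chol`` as 0/1
  etiology/demographic indicators), the observed time ``time`` (years) and
  the death indicator ``event``;
* a longitudinal table — one row per subject visit with the time-varying
  covariates: MELD-Na score (``meldna``), serum albumin (``albumin``,
  g/dL), a cumulative count of decompensating events (``decomp``) and a
  one-way hepatocellular-carcinoma indicator (``hcc``).

The true death model is proportional hazards in the *current* (last
observed, carried forward) covariate values, with a piecewise-constant
hazard between visits.  Because the data-generating hazard is known in
closed form, :func:`true_conditional_survival` and
:func:`true_conditional_rmst` serve as exact oracles for
parameter-recovery tests of the downstream landmark models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE_COLUMNS = ["age", "sex", "etoh", "biliary", "chol"]
LONGITUDINAL_COLUMNS = ["meldna", "albumin", "decomp", "hcc"]
#: covariates entering the prediction models (sex is generated but, as in
#: the reference analysis, not modelled)
MODEL_COVARIATES = ["age", "etoh", "biliary", "chol", "meldna", "albumin", "decomp", "hcc"]


@dataclass(frozen=True)
class TrajectoryParams:
    """Linear random-effects model for one biomarker.

    value at visit time t = (intercept + slope * t) + noise, with the
    intercept and slope drawn once per subject.
    """

    intercept_mean: float
    intercept_sd: float
    slope_mean: float
    slope_sd: float
    noise_sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def validate(self, name: str) -> None:
        for f in ("intercept_sd", "slope_sd", "noise_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{name}.{f} must be >= 0, got {getattr(self, f)}")


def _default_meldna() -> TrajectoryParams:
    return TrajectoryParams(15.0, 5.0, 0.6, 1.0, 2.0, lower=6.0, upper=40.0)


def _default_albumin() -> TrajectoryParams:
    return TrajectoryParams(3.3, 0.5, -0.06, 0.1, 0.25, lower=1.2, upper=5.5)


def _default_log_hr() -> dict[str, float]:
    # per-unit log hazard ratios for death on the current covariate values
    return {
        "age": 0.02,
        "sex": 0.0,
        "etoh": 0.10,
        "biliary": 0.10,
        "chol": 0.10,
        "meldna": 0.09,
        "albumin": -0.45,
        "decomp": 0.20,
        "hcc": 0.45,
    }


def _default_centers() -> dict[str, float]:
    # reference covariate values at which the baseline hazard applies
    return {"age": 60.0, "meldna": 15.0, "albumin": 3.4}


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    Rates are per year; times are years since study entry.  The defaults
    emulate a cirrhosis EHR cohort with roughly one fifth of subjects dying
    during follow-up and a median follow-up near one year; they are tuning
    targets of the scenario, not assertions about any single draw.
    """

    n_subjects: int = 1000
    age_mean: float = 60.0
    age_sd: float = 10.0
    p_sex: float = 0.5
    p_etoh: float = 0.35
    p_biliary: float = 0.08
    p_chol: float = 0.08
    meldna: TrajectoryParams = field(default_factory=_default_meldna)
    albumin: TrajectoryParams = field(default_factory=_default_albumin)
    visit_spacing: float = 0.25
    visit_jitter: float = 0.05
    decomp_rate: float = 0.3
    #: mean number of decompensating events in the pre-entry history
    baseline_decomp_mean: float = 0.25
    hcc_hazard: float = 0.04
    #: probability of prevalent HCC at study entry
    p_hcc0: float = 0.03
    log_hr: dict[str, float] = field(default_factory=_default_log_hr)
    hazard_centers: dict[str, float] = field(default_factory=_default_centers)
    baseline_hazard: float = 0.085
    censoring_hazard: float = 0.55
    admin_end: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        for f in ("p_sex", "p_etoh", "p_biliary", "p_chol"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if not 0.0 <= self.p_hcc0 <= 1.0:
            raise ValueError(f"p_hcc0 must be in [0, 1], got {self.p_hcc0}")
        for f in (
            "age_sd",
            "visit_jitter",
            "decomp_rate",
            "baseline_decomp_mean",
            "hcc_hazard",
            "baseline_hazard",
            "censoring_hazard",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0, got {getattr(self, f)}")
        for f in ("visit_spacing", "admin_end"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0, got {getattr(self, f)}")
        self.meldna.validate("meldna")
        self.albumin.validate("albumin")
        unknown = set(self.log_hr) - set(BASELINE_COLUMNS + LONGITUDINAL_COLUMNS)
        if unknown:
            raise ValueError(f"log_hr refers to unknown covariates: {sorted(unknown)}")

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """A simulated (or ingested) cohort as the two analysis tables."""

    survival: pd.DataFrame
    longitudinal: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def event_fraction(self) -> float:
        return float(self.survival["event"].mean())

    def validate(self) -> None:
        """Raise if any subject violates the record invariants."""
        surv = self.survival
        if (surv["time"] <= 0).any():
            raise ValueError("observed times must be positive")
        if not surv["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if surv["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in survival table")
        obs_time = surv.set_index("subject_id")["time"]
        for sid, grp in self.longitudinal.groupby("subject_id", sort=False):
            t = grp["time"].to_numpy()
            if not (np.diff(t) > 0).all():
                raise ValueError(f"measurement times not strictly increasing for {sid}")
            if t[-1] > obs_time.loc[sid] + 1e-12:
                raise ValueError(f"measurement after observed time for {sid}")
            if (np.diff(grp["decomp"].to_numpy()) < 0).any():
                raise ValueError(f"decomp count decreases for {sid}")
            if (np.diff(grp["hcc"].to_numpy()) < 0).any():
                raise ValueError(f"hcc indicator switches off for {sid}")

    def subset(self, subject_ids) -> "Cohort":
        ids = set(subject_ids)
        return Cohort(
            self.survival[self.survival["subject_id"].isin(ids)].reset_index(drop=True),
            self.longitudinal[self.longitudinal["subject_id"].isin(ids)].reset_index(drop=True),
        )

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.survival.to_csv(out / "survival.csv", index=False)
        self.longitudinal.to_csv(out / "longitudinal.csv", index=False)

    @classmethod
    def read(cls, out_dir) -> "Cohort":
        from pathlib import Path

        out = Path(out_dir)
        return cls(
            pd.read_csv(out / "survival.csv"),
            pd.read_csv(out / "longitudinal.csv"),
        )


def _log_hazard(params: CohortParams, cov: dict[str, float]) -> float:
    lp = np.log(params.baseline_hazard) if params.baseline_hazard > 0 else -np.inf
    for name, beta in params.log_hr.items():
        if beta == 0.0:
            continue  # covariates with no effect need not be on the path
        lp += beta * (cov[name] - params.hazard_centers.get(name, 0.0))
    return lp


def simulate_cohort(params: CohortParams) -> Cohort:
    """Simulate a cohort under the piecewise-constant covariate-driven hazard.

    Each subject gets an independent random stream spawned from the master
    seed, so the first k subjects are identical across runs that differ only
    in ``n_subjects``.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_subjects)
    surv_rows = []
    long_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = i + 1

        age = rng.normal(params.age_mean, params.age_sd)
        sex = int(rng.random() < params.p_sex)
        etoh = int(rng.random() < params.p_etoh)
        biliary = int(rng.random() < params.p_biliary)
        chol = int(rng.random() < params.p_chol)

        mp, ap = params.meldna, params.albumin
        b0 = rng.normal(mp.intercept_mean, mp.intercept_sd)
        b1 = rng.normal(mp.slope_mean, mp.slope_sd)
        a0 = rng.normal(ap.intercept_mean, ap.intercept_sd)
        a1 = rng.normal(ap.slope_mean, ap.slope_sd)
        hcc_onset = rng.exponential(1.0 / params.hcc_hazard) if params.hcc_hazard > 0 else np.inf
        if params.p_hcc0 > 0 and rng.random() < params.p_hcc0:
            hcc_onset = 0.0  # prevalent at entry
        censor = (
            rng.exponential(1.0 / params.censoring_hazard)
            if params.censoring_hazard > 0
            else np.inf
        )
        censor = min(censor, params.admin_end)
        target = rng.exponential(1.0)  # unit-exponential death target for H(t)

        base_cov = {"age": age, "sex": sex, "etoh": etoh, "biliary": biliary, "chol": chol}

        # walk the visit schedule (regular spacing with jitter, first visit
        # at entry), integrating the piecewise-constant hazard as we go;
        # stops at death or censoring, so no visits are generated past T
        meas = []
        t = 0.0
        cum = 0.0
        decomp = int(rng.poisson(params.baseline_decomp_mean))  # pre-entry history
        next_dec = (
            rng.exponential(1.0 / params.decomp_rate) if params.decomp_rate > 0 else np.inf
        )
        death = np.inf
        while True:
            while next_dec <= t:
                decomp += 1
                next_dec += rng.exponential(1.0 / params.decomp_rate)
            meld = float(np.clip(b0 + b1 * t + rng.normal(0, mp.noise_sd), mp.lower, mp.upper))
            alb = float(np.clip(a0 + a1 * t + rng.normal(0, ap.noise_sd), ap.lower, ap.upper))
            hcc = int(t >= hcc_onset)
            meas.append((t, meld, alb, decomp, hcc))
            h = np.exp(
                _log_hazard(
                    params,
                    {**base_cov, "meldna": meld, "albumin": alb, "decomp": decomp, "hcc": hcc},
                )
            )
            step = params.visit_spacing + rng.uniform(-params.visit_jitter, params.visit_jitter)
            next_t = t + max(step, 1e-6)
            stop = min(next_t, censor)
            if h > 0 and cum + h * (stop - t) >= target:
                death = t + (target - cum) / h
                break
            cum += h * (stop - t)
            if next_t >= censor:
                break
            t = next_t

        obs = min(death, censor)
        event = int(death <= censor)
        surv_rows.append((sid, obs, event, age, sex, etoh, biliary, chol))
        for t_k, meld_k, alb_k, dec_k, hcc_k in meas:
            if t_k <= obs:
                long_rows.append((sid, t_k, meld_k, alb_k, dec_k, hcc_k))

    survival = pd.DataFrame(
        surv_rows, columns=["subject_id", "time", "event"] + BASELINE_COLUMNS
    )
    longitudinal = pd.DataFrame(
        long_rows, columns=["subject_id", "time"] + LONGITUDINAL_COLUMNS
    )
    return Cohort(survival, longitudinal)


def _path_hazards(params: CohortParams, path: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "time" not in path.columns:
        raise ValueError("covariate path needs a 'time' column")
    needed = [c for c, b in params.log_hr.items() if b != 0.0]
    missing = [c for c in needed if c not in path.columns]
    if missing:
        raise KeyError(f"covariate path lacks columns with non-zero effects: {missing}")
    path = path.sort_values("time")
    times = path["time"].to_numpy(float)
    haz = np.array(
        [
            np.exp(_log_hazard(params, {c: row[c] for c in params.log_hr if c in path.columns}))
            for _, row in path.iterrows()
        ]
    )
    return times, haz


def true_conditional_survival(
    params: CohortParams, covariate_path: pd.DataFrame, ell: float, horizon: float
) -> float:
    """P(T > horizon | T > ell) under the generator's own hazard.

    ``covariate_path`` is a step function (rows = (time, covariates...),
    last value carried forward); it must start at or before ``ell``.
    """
    if horizon < ell:
        raise ValueError(f"horizon {horizon} < landmark {ell}")
    times, haz = _path_hazards(params, covariate_path)
    knots = np.concatenate([[ell], times[(times > ell) & (times < horizon)], [horizon]])
    idx = np.searchsorted(times, knots[:-1], side="right") - 1
    idx = np.clip(idx, 0, len(times) - 1)
    return float(np.exp(-np.sum(haz[idx] * np.diff(knots))))


def true_conditional_rmst(
    params: CohortParams, covariate_path: pd.DataFrame, ell: float, tau: float
) -> float:
    """E[min(T - ell, tau) | T > ell]: integral of the conditional survival.

    Exact segment-by-segment integration of the piecewise-exponential
    survival curve (no quadrature error).
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if tau == 0:
        return 0.0
    times, haz = _path_hazards(params, covariate_path)
    end = ell + tau
    knots = np.concatenate([[ell], times[(times > ell) & (times < end)], [end]])
    idx = np.searchsorted(times, knots[:-1], side="right") - 1
    idx = np.clip(idx, 0, len(times) - 1)
    total = 0.0
    surv = 1.0
    for a, b, h in zip(knots[:-1], knots[1:], haz[idx]):
        width = b - a
        if h > 0:
            total += surv * (1.0 - np.exp(-h * width)) / h
            surv *= np.exp(-h * width)
        else:
            total += surv * width
    return float(total)
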