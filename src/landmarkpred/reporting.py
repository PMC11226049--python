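"""End-to-end pipeline orchestration and figures.

The pipeline runs: simulate (or ingest) -> subject-level split ->
landmark stacking -> pseudo-outcomes -> dynamic + static fits ->
held-out evaluation -> coefficient tables, metric tables and figures.
Every plotted value is recomputable from the emitted tables; figures are
views, never the only record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortParams, MODEL_COVARIATES, simulate_cohort
from .evaluation import evaluate_over_landmarks, split_train_test
from .landmark import LandmarkGrid, make_landmark_grid, stack_landmark_datasets
from .models import (
    FittedSupermodel,
    StaticModelSet,
    coefficient_table,
    fit_cox_supermodel,
    fit_gee_supermodel,
    fit_static_model,
)
from .pseudo import attach_pseudo_outcomes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    n_subjects: int = 500
    cohort_overrides: dict = field(default_factory=dict)
    grid_start: float = 0.0
    grid_end: float = 5.0
    grid_step: float = 0.5
    tau: float = 3.0
    time_scale: float = 5.0
    families: list = field(default_factory=lambda: ["PM", "PP", "cox"])
    static_variants: list = field(default_factory=lambda: ["SM1", "SM2", "SM3"])
    covariates: list = field(default_factory=lambda: list(MODEL_COVARIATES))
    split_fraction: float = 0.75
    seed: int = 0
    out_dir: str = "landmarkpred_run"
    input_dir: str | None = None  # read survival.csv/longitudinal.csv instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def make_grid(self) -> LandmarkGrid:
        return make_landmark_grid(
            self.grid_start, self.grid_end, self.grid_step, self.tau, self.time_scale
        )


def plot_dynamic_coefficients(
    model: FittedSupermodel, covariates: list[str], grid: LandmarkGrid, path
) -> Path:
    """One panel per covariate: beta_p(ell) with its 95% band over the grid."""
    unknown = [c for c in covariates if c not in model.covariates]
    if unknown:
        raise KeyError(f"not fitted: {unknown}")
    ells = np.linspace(grid.times[0], grid.times[-1], 101)
    ncol = min(4, len(covariates))
    nrow = int(np.ceil(len(covariates) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax, cov in zip(axes.ravel(), covariates):
        vals = [model.dynamic_coefficient(cov, e) for e in ells]
        ax.plot(ells, [v.value for v in vals], "k-")
        ax.plot(ells, [v.ci_low for v in vals], "k--", lw=0.8)
        ax.plot(ells, [v.ci_high for v in vals], "k--", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(cov)
        ax.set_xlabel("landmark time (years)")
    for ax in axes.ravel()[len(covariates):]:
        ax.set_visible(False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_individual_trajectories(
    dynamic: FittedSupermodel,
    static: StaticModelSet,
    cohort: Cohort,
    subject_ids,
    grid: LandmarkGrid,
    covariates: list[str],
    path,
) -> tuple[Path, pd.DataFrame]:
    """Per-subject dynamic (solid) vs static (dashed) conditional predictions.

    The trajectory stops at the last landmark where the subject is still at
    risk.  Returns the figure path and the plotted values as a table.
    """
    from .landmark import build_landmark_dataset

    records = []
    for ell in grid.times:
        data = build_landmark_dataset(cohort, float(ell), grid.tau, covariates=covariates)
        data = data[data["subject_id"].isin(subject_ids)]
        for _, row in data.iterrows():
            X = row[covariates].to_frame().T.astype(float)
            records.append(
                {
                    "subject_id": row["subject_id"],
                    "landmark": float(ell),
                    "dynamic": float(dynamic.predict(X, float(ell))[0]),
                    "static": float(static.predict(X, float(ell))[0]),
                }
            )
    table = pd.DataFrame(records)
    plotted = [s for s in subject_ids if s in set(table["subject_id"])]
    skipped = [s for s in subject_ids if s not in set(table["subject_id"])]
    if skipped:
        logger.warning("subjects never at risk, skipped: %s", skipped)
    fig, axes = plt.subplots(1, max(len(plotted), 1), figsize=(4 * max(len(plotted), 1), 3), squeeze=False)
    for ax, sid in zip(axes.ravel(), plotted):
        sub = table[table["subject_id"] == sid]
        ax.plot(sub["landmark"], sub["dynamic"], "-", label="dynamic")
        ax.plot(sub["landmark"], sub["static"], "--", label="static")
        ax.set_title(f"subject {sid}")
        ax.set_xlabel("landmark time (years)")
        ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path, table


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Writes the cohort tables, the stacked landmark table per family, the
    coefficient tables, the held-out metric table, the figures and a JSON
    manifest with seeds and per-stage row counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.input_dir:
        cohort = Cohort.read(config.input_dir)
    else:
        params = CohortParams(
            n_subjects=config.n_subjects, seed=config.seed, **config.cohort_overrides
        )
        cohort = simulate_cohort(params)
    cohort.validate()
    cohort.write(out / "cohort")
    manifest["stages"]["cohort"] = {
        "n_subjects": cohort.n_subjects,
        "event_fraction": cohort.event_fraction,
    }

    grid = config.make_grid()
    train, test = split_train_test(cohort, config.split_fraction, config.seed)
    manifest["stages"]["split"] = {"n_train": train.n_subjects, "n_test": test.n_subjects}

    stacked = stack_landmark_datasets(grid, train, covariates=config.covariates)
    per_landmark = stacked.groupby("landmark").size()
    manifest["stages"]["landmarking"] = {
        "n_rows": len(stacked),
        "rows_per_landmark": {f"{k:g}": int(v) for k, v in per_landmark.items()},
        "conserved": bool(len(stacked) == int(per_landmark.sum())),
    }
    stacked.to_csv(out / "stacked_train.csv", index=False)

    models: dict[str, object] = {}
    for fam in config.families:
        if fam == "cox":
            fitted = fit_cox_supermodel(stacked, config.covariates, grid.tau, time_scale=config.time_scale)
        else:
            with_po = attach_pseudo_outcomes(stacked, grid.tau, kind="mean" if fam == "PM" else "prob")
            with_po.to_csv(out / f"stacked_train_pseudo_{fam}.csv", index=False)
            fitted = fit_gee_supermodel(
                with_po, config.covariates, grid.tau, time_scale=config.time_scale, family=fam
            )
        models[f"dynamic_{fam}"] = fitted
        coefficient_table(fitted).to_csv(out / f"coefficients_dynamic_{fam}.csv", index=False)
        for variant in config.static_variants:
            models[f"{variant}_{fam}"] = fit_static_model(
                variant, fam, train, grid, config.covariates
            )
    manifest["stages"]["fit"] = {"models": sorted(models)}

    metrics = evaluate_over_landmarks(models, test, grid, config.covariates)
    metrics.to_csv(out / "metrics.csv", index=False)
    manifest["stages"]["evaluate"] = {"n_rows": len(metrics)}

    for fam in config.families:
        if fam in ("PM", "PP"):
            plot_dynamic_coefficients(
                models[f"dynamic_{fam}"], config.covariates, grid, out / f"dynamic_coefficients_{fam}.png"
            )
    if "PM" in config.families and "SM2" in config.static_variants:
        ids = list(test.survival.sort_values("time", ascending=False)["subject_id"].head(2))
        _, traj = plot_individual_trajectories(
            models["dynamic_PM"], models["SM2_PM"], test, ids, grid,
            config.covariates, out / "individual_trajectories_PM.png",
        )
        traj.to_csv(out / "individual_trajectories_PM.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
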