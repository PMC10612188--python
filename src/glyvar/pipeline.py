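"""End-to-end analysis pipeline.

One declarative config drives: cohort simulation (or loading delimited
visit/patient files), eligibility filtering, variability metrics,
clustering with k selection, low/medium/high group ordering, stratified
treatment hazard ratios with interaction and trend tests, two-piecewise
threshold analysis of mean HbA1c per group, smooth dose-response
curves, and the VIM sensitivity variant — with a machine-readable
manifest recording seeds, versions, and per-patient exclusions.

All randomness flows from ``RunConfig.seed``; running the same config
twice produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aft import stratified_treatment_hr
from .cluster import (
    GROUP_NAMES,
    kmeans_fit,
    kmedians_fit,
    order_clusters,
    quantile_clusters,
    select_k,
    standardize,
    validation_scores,
)
from .cohort import CohortParams, generate_cohort
from .io import read_patients, read_visits, write_table
from .metrics import compute_metrics, fit_vim_model, vim
from .smooth import curve_report, fit_smooth_hr
from .threshold import threshold_analysis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "apply_eligibility", "run_full_analysis"]

DEFAULT_COVARIATE_NAMES = ["age", "female", "bmi", "sbp", "egfr", "smoker"]


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    simulate: CohortParams | None = None
    visits_path: str | None = None
    patients_path: str | None = None
    hvs_denominator: str = "intervals"
    cluster_methods: tuple[str, ...] = ("kmeans", "kmedians", "quantile")
    scale: str = "zscore"  # zscore | none
    k_range: tuple[int, int] = (2, 9)
    n_init: int = 20
    outcomes: tuple[str, ...] = ("mace", "death")
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATE_NAMES))
    min_followup_years: float = 0.0
    use_vim: bool = False
    quantile_feature: str = "hvs"
    silhouette_sample: int | None = 2000
    n_boot: int = 200
    grid_step: float = 0.01
    smooth_df: int = 4
    smooth_per_group: bool = True
    threshold_enabled: bool = True
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if not (2 <= lo <= hi <= 9):
            raise ValueError("k_range must lie within [2, 9]")
        if self.min_followup_years < 0:
            raise ValueError("min_followup_years must be >= 0")
        if self.simulate is None and (self.visits_path is None or self.patients_path is None):
            raise ValueError("config needs either a simulate block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            for tup_key in ("arm_targets", "visit_schedule"):
                if tup_key in sim:
                    sim[tup_key] = tuple(sim[tup_key])
            if "volatility_mixture" in sim:
                sim["volatility_mixture"] = tuple(tuple(p) for p in sim["volatility_mixture"])
            raw["simulate"] = CohortParams(**sim)
        for tup_key in ("cluster_methods", "k_range", "outcomes"):
            if tup_key in raw and raw[tup_key] is not None:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_eligibility(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    min_followup_years: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Eligibility filter with a per-patient exclusion log.

    Drops patients with fewer than two HbA1c measurements (variability
    score incomputable) and, when ``min_followup_years > 0``
    (sensitivity mode), patients with shorter follow-up.  Orphan visits
    (no matching patient record) are an error.

    Returns ``(visits, patients, exclusions)`` where ``exclusions`` has
    columns ``patient_id, reason``.
    """
    pids = set(patients["patient_id"])
    orphan = ~visits["patient_id"].isin(pids)
    if orphan.any():
        ids = sorted(pd.unique(visits.loc[orphan, "patient_id"]))
        raise ValueError(
            f"{len(ids)} visit patient_ids lack patient records (e.g. {ids[:10]})"
        )
    counts = visits.groupby("patient_id").size()
    n_measures = patients["patient_id"].map(counts).fillna(0).astype(int)

    reasons: list[tuple[object, str]] = []
    drop = n_measures < 2
    for pid in patients.loc[drop.to_numpy(), "patient_id"]:
        reasons.append((pid, "hvs_incomputable"))
    if min_followup_years > 0:
        followup_col = "time_death" if "time_death" in patients.columns else None
        if followup_col is None:
            time_cols = [c for c in patients.columns if c.startswith("time_")]
            if not time_cols:
                raise ValueError("no follow-up time column found")
            followup = patients[time_cols].max(axis=1)
        else:
            followup = patients[followup_col]
        short = (followup < min_followup_years) & ~drop.to_numpy()
        for pid in patients.loc[short.to_numpy(), "patient_id"]:
            reasons.append((pid, "short_followup"))
        drop = drop.to_numpy() | short.to_numpy()
    else:
        drop = drop.to_numpy()

    exclusions = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    kept = patients.loc[~drop].reset_index(drop=True)
    kept_visits = visits[visits["patient_id"].isin(set(kept["patient_id"]))].reset_index(
        drop=True
    )
    logger.info(
        "eligibility: kept %d of %d patients (%d excluded)",
        len(kept), len(patients), int(drop.sum()),
    )
    return kept_visits, kept, exclusions


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    metrics: pd.DataFrame
    assignments: pd.DataFrame
    validation: pd.DataFrame
    group_summary: pd.DataFrame
    treatment_effects: pd.DataFrame
    threshold_report: pd.DataFrame
    curves: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict

    _FILES = {
        "metrics": "metrics.csv",
        "assignments": "assignments.csv",
        "validation": "validation_scores.csv",
        "group_summary": "group_summary.csv",
        "treatment_effects": "treatment_effects.csv",
        "threshold_report": "threshold_report.csv",
        "curves": "smooth_curves.csv",
        "exclusions": "exclusions.csv",
    }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            write_table(getattr(self, attr), out / fname)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise StageError(f"pipeline stage '{name}' failed: {e}") from e
        return wrapper
    return deco


def _child_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def _ordered_group_labels(method, features, metrics, cfg, k=3):
    """Fit a 3-cluster model and return per-patient low/medium/high names."""
    if method == "quantile":
        labels = quantile_clusters(metrics[cfg.quantile_feature].to_numpy(), 3)
        names = np.asarray(GROUP_NAMES, dtype=object)[labels]
        return names, None
    if cfg.scale == "zscore":
        Z, scaling = standardize(features)
    else:
        Z, scaling = features.to_numpy(dtype=float), None
    fitter = kmeans_fit if method == "kmeans" else kmedians_fit
    model = fitter(Z, k, seed=_child_seed(cfg.seed, 10), n_init=cfg.n_init, scaling=scaling)
    order_clusters(model, metrics["hvs"].to_numpy())
    return model.group_names(), model


def run_full_analysis(config: RunConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the whole analysis; optionally write the bundle to ``out_dir``."""
    cfg = config
    manifest: dict = {
        "glyvar_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "notes": [],
    }

    # ---- input ------------------------------------------------------
    @_stage("input")
    def _load():
        if cfg.simulate is not None:
            cohort = generate_cohort(cfg.simulate)
            return cohort.visits, cohort.patients
        return read_visits(cfg.visits_path), read_patients(cfg.patients_path)

    visits, patients = _load()
    n_input = len(patients)

    # ---- eligibility ------------------------------------------------
    @_stage("eligibility")
    def _elig():
        return apply_eligibility(visits, patients, cfg.min_followup_years)

    visits_f, patients_f, exclusions = _elig()
    manifest["n_input_patients"] = n_input
    manifest["n_included"] = len(patients_f)
    manifest["n_excluded"] = len(exclusions)
    manifest["exclusion_reasons"] = (
        exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
    )

    # ---- metrics ----------------------------------------------------
    @_stage("metrics")
    def _metrics():
        m = compute_metrics(visits_f, hvs_denominator=cfg.hvs_denominator)
        vm = fit_vim_model(m)
        m["vim"] = vim(m, vm)
        return m, vm

    metrics, vim_model = _metrics()
    manifest["vim_model"] = {
        "exponent_x": vim_model.exponent_x,
        "population_mean": vim_model.population_mean,
        "fit_r2": vim_model.fit_r2,
        "n_patients_fit": vim_model.n_patients_fit,
    }

    # ---- clustering -------------------------------------------------
    @_stage("clustering")
    def _cluster():
        features = metrics[["hvs", "sd"]]
        Z, _ = standardize(features) if cfg.scale == "zscore" else (
            features.to_numpy(dtype=float), None)
        val_rows, chosen = [], {}
        for method in cfg.cluster_methods:
            if method == "quantile":
                continue
            table, k_star = select_k(
                Z,
                k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                method=method,
                seed=_child_seed(cfg.seed, 20),
                n_init=cfg.n_init,
                silhouette_sample=cfg.silhouette_sample,
            )
            val_rows.append(table)
            chosen[method] = k_star
        validation = (
            pd.concat(val_rows, ignore_index=True)
            if val_rows
            else pd.DataFrame(columns=["method", "k", "calinski_harabasz", "davies_bouldin", "silhouette"])
        )
        assign_frames = {}
        for method in cfg.cluster_methods:
            names, _model = _ordered_group_labels(method, features, metrics, cfg)
            assign_frames[method] = names
        return validation, chosen, assign_frames

    validation, chosen_k, assign_frames = _cluster()
    manifest["chosen_k"] = chosen_k

    assignments = pd.DataFrame({"patient_id": metrics["patient_id"]})
    for method, names in assign_frames.items():
        assignments[method] = names
    primary_method = cfg.cluster_methods[0]
    groups = assignments[primary_method].to_numpy()
    manifest["group_sizes"] = {
        m: {g: int((assignments[m] == g).sum()) for g in GROUP_NAMES}
        for m in assign_frames
    }

    # ---- analysis table --------------------------------------------
    patients_a = patients_f.merge(metrics, on="patient_id", how="inner")
    cov_names = [c for c in cfg.covariates if c in patients_a.columns]
    if missing := [c for c in cfg.covariates if c not in patients_a.columns]:
        manifest["notes"].append(f"covariates absent from data, skipped: {missing}")

    # ---- group summary ---------------------------------------------
    @_stage("group_summary")
    def _summary():
        baseline = (
            visits_f.sort_values(["patient_id", "month"], kind="stable")
            .groupby("patient_id", sort=False)["hba1c"]
            .first()
        )
        df = patients_a.assign(
            group=groups, baseline_hba1c=patients_a["patient_id"].map(baseline)
        )
        rows = []
        for g in GROUP_NAMES:
            sub = df[df["group"] == g]
            row = {
                "group": g,
                "n": len(sub),
                "hvs_mean": sub["hvs"].mean(),
                "hvs_sd": sub["hvs"].std(),
                "sd_mean": sub["sd"].mean(),
                "sd_sd": sub["sd"].std(),
                "mean_hba1c_mean": sub["mean_hba1c"].mean(),
                "baseline_hba1c_mean": sub["baseline_hba1c"].mean(),
                "baseline_hba1c_sd": sub["baseline_hba1c"].std(),
                "pct_intensive": 100.0 * (sub["arm"] == "intensive").mean(),
            }
            for oc in cfg.outcomes:
                row[f"crude_{oc}_pct"] = 100.0 * sub[f"event_{oc}"].mean()
            rows.append(row)
        return pd.DataFrame(rows)

    group_summary = _summary()

    # ---- stratified treatment effects -------------------------------
    @_stage("treatment_effects")
    def _effects():
        rows = []
        for method in assign_frames:
            grp = assignments[method].to_numpy()
            for oc in cfg.outcomes:
                res = stratified_treatment_hr(patients_a, grp, oc, cov_names)
                for g in GROUP_NAMES:
                    hr = res.per_group[g]
                    rows.append(
                        {
                            "method": method,
                            "outcome": oc,
                            "group": g,
                            "hr": hr.hr,
                            "ci_low": hr.ci_low,
                            "ci_high": hr.ci_high,
                            "p": hr.p_value,
                            "n": res.n_by_group[g],
                            "n_events": res.events_by_group[g],
                            "interaction_p": res.interaction_p,
                            "trend_p": res.trend_p,
                        }
                    )
        return pd.DataFrame(rows)

    treatment_effects = _effects()

    # ---- threshold analysis ----------------------------------------
    @_stage("threshold")
    def _threshold():
        rows = []
        if not cfg.threshold_enabled:
            return pd.DataFrame(rows)
        cells = [(g, groups == g) for g in GROUP_NAMES] + [
            ("total", np.ones(len(patients_a), dtype=bool))
        ]
        for i, (label, mask) in enumerate(cells):
            for j, oc in enumerate(cfg.outcomes):
                sub = patients_a.loc[mask].reset_index(drop=True)
                tf = threshold_analysis(
                    sub,
                    exposure="mean_hba1c",
                    outcome=oc,
                    covariates=["treatment"] + cov_names,
                    n_boot=cfg.n_boot,
                    seed=_child_seed(cfg.seed, 100 + 10 * i + j),
                    grid_step=cfg.grid_step,
                )
                rows.append(
                    {
                        "outcome": oc,
                        "group": label,
                        "n": tf.n,
                        "n_events": tf.n_events,
                        "hr_onepiece": tf.hr_onepiece.hr,
                        "hr_onepiece_lo": tf.hr_onepiece.ci_low,
                        "hr_onepiece_hi": tf.hr_onepiece.ci_high,
                        "p_onepiece": tf.hr_onepiece.p_value,
                        "inflection_k": tf.inflection_k,
                        "k_ci_low": tf.k_ci[0] if tf.k_ci else np.nan,
                        "k_ci_high": tf.k_ci[1] if tf.k_ci else np.nan,
                        "hr_below": tf.hr_below.hr,
                        "hr_below_lo": tf.hr_below.ci_low,
                        "hr_below_hi": tf.hr_below.ci_high,
                        "p_below": tf.hr_below.p_value,
                        "hr_above": tf.hr_above.hr,
                        "hr_above_lo": tf.hr_above.ci_low,
                        "hr_above_hi": tf.hr_above.ci_high,
                        "p_above": tf.hr_above.p_value,
                        "p_curvature": tf.p_curvature,
                        "events_below": tf.events_below,
                        "events_above": tf.events_above,
                        "sparse_below": tf.sparse_below,
                        "sparse_above": tf.sparse_above,
                    }
                )
        return pd.DataFrame(rows)

    threshold_report = _threshold()

    # ---- smooth curves ----------------------------------------------
    @_stage("smooth_curves")
    def _curves():
        frames = []
        cells = [("total", np.ones(len(patients_a), dtype=bool))]
        if cfg.smooth_per_group:
            cells += [(g, groups == g) for g in GROUP_NAMES]
        for label, mask in cells:
            for oc in cfg.outcomes:
                sub = patients_a.loc[mask].reset_index(drop=True)
                try:
                    curve = fit_smooth_hr(
                        sub,
                        exposure="mean_hba1c",
                        outcome=oc,
                        covariates=["treatment"] + cov_names,
                        df=cfg.smooth_df,
                    )
                except ValueError as e:
                    manifest["notes"].append(f"smooth curve skipped ({label}, {oc}): {e}")
                    continue
                rep = curve_report(curve)
                rep.insert(0, "group", label)
                frames.append(rep)
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["group", "exposure", "outcome", "value", "hr", "ci_low", "ci_high", "is_reference"]
            )
        )

    curves = _curves()

    # ---- VIM sensitivity -------------------------------------------
    if cfg.use_vim:
        @_stage("vim_sensitivity")
        def _vim_cluster():
            names, _ = _ordered_group_labels(
                "kmeans", metrics[["hvs", "vim"]], metrics, cfg
            )
            return names

        vim_names = _vim_cluster()
        assignments["kmeans_vim"] = vim_names
        if "kmeans" in assignments.columns:
            agree = float((assignments["kmeans_vim"] == assignments["kmeans"]).mean())
            manifest["vim_kmeans_agreement"] = agree

    bundle = ReportBundle(
        metrics=metrics,
        assignments=assignments,
        validation=validation,
        group_summary=group_summary,
        treatment_effects=treatment_effects,
        threshold_report=threshold_report,
        curves=curves,
        exclusions=exclusions,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
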