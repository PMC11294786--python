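"""End-to-end study orchestration: simulate -> extract -> QC -> aggregate ->
screen -> classify -> report.

`run_study` executes the whole analysis on a simulated cohort and returns a
:class:`StudyReport` whose tables mirror the evaluation layout of the study:
per-timescale and per-category logistic models scored at probability 0.5,
single-feature models at the 7-day timescale, and raw-scale Youden cutoffs for
the leading features. Every stage's intermediate table can be persisted as CSV
so stages are independently inspectable, and the whole run is deterministic
under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import TIMESCALES, build_samples
from .datatypes import FEATURE_CATEGORIES, FEATURE_COLUMNS, SimulationConfig
from .diagnostics import (
    PerfectSeparationError,
    RocResult,
    fit_logistic,
    roc_evaluate,
    screen_features,
)
from .hrv import extract_features
from .qc import QcThresholds, filter_nights
from .simulate import generate_cohort, generate_feature_cohort, roster_to_frame

logger = logging.getLogger("noctivitals")

__all__ = ["StudyConfig", "StudyReport", "PipelineStageError", "run_study"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated diagnostic study."""

    simulation: SimulationConfig = SimulationConfig()
    timescales: tuple[int, ...] = TIMESCALES
    alpha: float = 0.05
    mode: str = "feature"  # "feature" (fast sampler) or "signal" (full synthesis)
    adjust_covariates: bool = False
    cross_validate: bool = False
    cv_folds: int = 5
    single_feature_timescale: int = 7
    cutoff_features: tuple[str, ...] = ("hf", "rr_mode", "rrf")
    qc_thresholds: QcThresholds = QcThresholds()

    def __post_init__(self) -> None:
        if self.mode not in ("feature", "signal"):
            raise ValueError("mode must be 'feature' or 'signal'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class StudyReport:
    """All study outputs plus provenance.

    ``evaluation`` holds one row per (feature set, timescale) model;
    ``single_features`` one row per single-feature model at the chosen
    timescale; ``cutoffs`` the raw-scale Youden cutoffs of the leading
    features. Every metric is recomputable from the persisted intermediates.
    """

    evaluation: pd.DataFrame
    single_features: pd.DataFrame
    cutoffs: pd.DataFrame
    screening: pd.DataFrame
    qc_summary: dict
    sample_counts: dict
    provenance: dict
    nightly_features: pd.DataFrame = field(repr=False, default=None)
    qc_decisions: pd.DataFrame = field(repr=False, default=None)
    samples: dict = field(repr=False, default_factory=dict)

    def summary_json(self) -> str:
        """Deterministic JSON digest of the report's result tables."""
        payload = {
            "evaluation": self.evaluation.round(10).to_dict("records"),
            "single_features": self.single_features.round(10).to_dict("records"),
            "cutoffs": self.cutoffs.round(10).to_dict("records"),
            "qc_summary": self.qc_summary,
            "sample_counts": {str(k): v for k, v in self.sample_counts.items()},
        }
        return json.dumps(payload, sort_keys=True, default=str)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.nightly_features is not None:
            self.nightly_features.to_csv(out / "nightly_features.csv", index=False)
        if self.qc_decisions is not None:
            self.qc_decisions.to_csv(out / "qc_decisions.csv", index=False)
        for t, frame in self.samples.items():
            frame.to_csv(out / f"samples_t{t}.csv", index=False)
        self.evaluation.to_csv(out / "evaluation.csv", index=False)
        for t in sorted(set(self.evaluation["t"].dropna())):
            sub = self.evaluation[self.evaluation["t"] == t]
            sub.to_csv(out / f"evaluation_t{int(t)}.csv", index=False)
        self.single_features.to_csv(out / "single_features.csv", index=False)
        self.cutoffs.to_csv(out / "cutoffs.csv", index=False)
        self.screening.to_csv(out / "screening.csv", index=False)
        meta = {
            "qc_summary": self.qc_summary,
            "sample_counts": {str(k): v for k, v in self.sample_counts.items()},
            "provenance": self.provenance,
        }
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))


def _config_hash(config: StudyConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


_COVARIATE_COLUMNS = ("age", "sex_male", "bmi_low", "bmi_high")


def _covariate_frame(roster: pd.DataFrame) -> pd.DataFrame:
    people = roster.drop_duplicates("participant_id").set_index("participant_id")
    return pd.DataFrame(
        {
            "age": people["age"].astype(float),
            "sex_male": (people["sex"] == "male").astype(float),
            "bmi_low": (people["bmi_category"] == "<18.5").astype(float),
            "bmi_high": (people["bmi_category"] == ">=24").astype(float),
        }
    )


def _drop_collinear(
    frame: pd.DataFrame, features: Sequence[str], min_tolerance: float = 1e-4
) -> list[str]:
    """Sequential tolerance screen: drop features explained by earlier ones.

    A feature whose tolerance (1 - R^2 against the already-accepted set)
    falls below ``min_tolerance`` is removed before the logistic fit — the
    same guard SPSS-style logistic applies. Here it prunes near-duplicates
    such as a long-window total power against the sum of its band powers.
    """
    accepted: list[str] = []
    X = frame[list(features)].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    for j, name in enumerate(features):
        if not accepted:
            if X[:, j].std() > 0:
                accepted.append(name)
            continue
        basis = X[:, [features.index(a) for a in accepted]]
        design = np.column_stack([np.ones(len(X)), basis])
        resid = X[:, j] - design @ np.linalg.lstsq(design, X[:, j], rcond=None)[0]
        tolerance = float(resid @ resid) / max(float(X[:, j] @ X[:, j]), 1e-300)
        if tolerance >= min_tolerance:
            accepted.append(name)
        else:
            logger.info("dropping near-collinear feature %s (tolerance %.2e)",
                        name, tolerance)
    return accepted


def _capped_logistic_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_eval: np.ndarray
) -> np.ndarray:
    """Probabilities from an iteration-capped quasi-Newton logistic fit.

    Used when the likelihood is unbounded (separation): the diverging
    coefficient direction still ranks the samples, which is all the ROC needs.
    """
    import statsmodels.api as sm

    mean = X_train.mean(axis=0)
    scale = np.where(X_train.std(axis=0) == 0, 1.0, X_train.std(axis=0))
    design = sm.add_constant((X_train - mean) / scale, has_constant="add")
    with np.errstate(all="ignore"):
        result = sm.Logit(y_train, design).fit(method="lbfgs", maxiter=200, disp=0)
    eval_design = sm.add_constant((X_eval - mean) / scale, has_constant="add")
    return np.asarray(result.predict(eval_design), dtype=float)


def _fold_scores(X_train, y_train, X_eval) -> np.ndarray:
    try:
        model = fit_logistic(X_train, y_train)
    except PerfectSeparationError:
        return _capped_logistic_scores(
            X_train.to_numpy(dtype=float), y_train, X_eval.to_numpy(dtype=float)
        )
    return model.predict_proba(X_eval.to_numpy(dtype=float))


def _model_scores(
    frame: pd.DataFrame,
    features: Sequence[str],
    config: StudyConfig,
) -> tuple[np.ndarray, str]:
    """Fitted (or out-of-fold) case probabilities for one feature set.

    Falls back to the raw feature as an ordinal score if a single feature
    separates the classes perfectly (the likelihood is then unbounded but the
    ranking — hence the ROC — is still well defined).
    """
    if len(features) > 1:
        features = _drop_collinear(frame, list(features))
    X = frame[list(features)]
    y = (frame["group"] == "case").astype(int).to_numpy()
    if config.cross_validate:
        from sklearn.model_selection import StratifiedKFold

        scores = np.empty(len(y))
        splitter = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True,
            random_state=config.simulation.seed,
        )
        for train, test in splitter.split(X, y):
            scores[test] = _fold_scores(X.iloc[train], y[train], X.iloc[test])
        return scores, "probability"
    try:
        model = fit_logistic(X, y)
    except PerfectSeparationError:
        if len(features) == 1:
            logger.warning(
                "feature %s separates the classes; using raw values as scores",
                features[0],
            )
            return frame[features[0]].to_numpy(dtype=float), "youden"
        logger.warning(
            "separation in %d-feature model; scoring by capped quasi-Newton fit",
            len(features),
        )
        Xa = X.to_numpy(dtype=float)
        return _capped_logistic_scores(Xa, y, Xa), "probability"
    return model.fitted_probabilities, "probability"


def _evaluation_row(name: str, t, features, result: RocResult, n: int) -> dict:
    return {
        "feature_set": name,
        "t": t,
        "n_samples": n,
        "n_features": len(features),
        "accuracy": result.accuracy,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "youden_index": result.youden_index,
        "auc": result.auc,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "p_value": result.p_value,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline on one simulated cohort."""
    sim = config.simulation

    # ---- simulate / extract -------------------------------------------------
    try:
        if config.mode == "signal":
            roster_objs, recordings = generate_cohort(sim)
            roster = roster_to_frame(roster_objs)
            nights = extract_features(recordings)
        else:
            roster, nights = generate_feature_cohort(sim)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate/extract", str(exc)) from exc
    logger.info("simulated %d recorded nights", len(nights))

    group_map = roster.drop_duplicates("participant_id").set_index("participant_id")[
        "group"
    ]

    # ---- QC -----------------------------------------------------------------
    try:
        kept, decisions = filter_nights(nights, roster, config.qc_thresholds)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("qc", str(exc)) from exc
    reason_counts: dict[str, int] = {}
    for reasons in decisions.loc[~decisions["kept"], "reasons"]:
        for reason in reasons.split("|"):
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
    qc_summary = {
        "nights_recorded": int(len(nights)),
        "nights_kept": int(len(kept)),
        "nights_excluded": int(len(nights) - len(kept)),
        "excluded_by_reason": reason_counts,
    }
    logger.info("QC kept %d / %d nights", len(kept), len(nights))

    covariates = _covariate_frame(roster) if config.adjust_covariates else None

    # ---- aggregate ----------------------------------------------------------
    samples: dict[int, pd.DataFrame] = {}
    for t in config.timescales:
        try:
            frame = build_samples(kept, t)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"aggregate t={t}", str(exc)) from exc
        frame["group"] = frame["participant_id"].map(group_map)
        if covariates is not None:
            frame = frame.join(covariates, on="participant_id")
        samples[t] = frame
        logger.info("t=%d: %d samples", t, len(frame))
    sample_counts = {t: int(len(samples[t])) for t in config.timescales}

    # ---- screen -------------------------------------------------------------
    # One screening decision for the whole study, taken on the shortest-window
    # samples and applied to every timescale: nightly samples are (close to)
    # exchangeable, whereas overlapping rolling windows at large t share most
    # of their nights and would wreck the rank test's independence assumption.
    # A feature indistinguishable between the groups is excluded everywhere.
    usable = [
        t
        for t in config.timescales
        if len(samples[t]) >= 10 and samples[t]["group"].nunique() == 2
    ]
    if not usable:
        raise PipelineStageError(
            "screen", "no timescale has enough person-time samples in both groups"
        )
    t_screen = min(usable)
    screen = screen_features(samples[t_screen], FEATURE_COLUMNS, alpha=config.alpha)
    retained: dict[int, tuple[str, ...]] = {
        t: screen.retained for t in config.timescales
    }
    screen_rows = [
        {
            "feature": feature,
            "t": t_screen,
            "p_value": screen.p_values[feature],
            "retained": feature in screen.retained,
        }
        for feature in FEATURE_COLUMNS
    ]
    logger.info(
        "screen at t=%d retained %d/%d features",
        t_screen, len(screen.retained), len(FEATURE_COLUMNS),
    )

    def with_covariates(features) -> list[str]:
        extra = list(_COVARIATE_COLUMNS) if covariates is not None else []
        return list(features) + extra

    # ---- per-timescale and per-category models ------------------------------
    eval_rows = []
    for t in usable:
        frame = samples[t]
        feats = with_covariates(retained[t])
        try:
            scores, rule = _model_scores(frame, feats, config)
            result = roc_evaluate(scores, frame["group"].to_numpy(), rule)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"evaluate all t={t}", str(exc)) from exc
        eval_rows.append(_evaluation_row("all", t, feats, result, len(frame)))

        for category, members in FEATURE_CATEGORIES.items():
            cat_feats = [f for f in members if f in retained[t]]
            if not cat_feats:
                continue
            try:
                scores, rule = _model_scores(frame, with_covariates(cat_feats), config)
                result = roc_evaluate(scores, frame["group"].to_numpy(), rule)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(
                    f"evaluate {category} t={t}", str(exc)
                ) from exc
            eval_rows.append(
                _evaluation_row(category, t, cat_feats, result, len(frame))
            )

    # ---- combined model across all timescales -------------------------------
    merged: Optional[pd.DataFrame] = None
    for t in usable:
        cols = ["participant_id", "anchor_night_date", *retained[t]]
        part = samples[t][cols].rename(
            columns={f: f"{f}_t{t}" for f in retained[t]}
        )
        merged = part if merged is None else merged.merge(
            part, on=["participant_id", "anchor_night_date"], how="inner"
        )
    if merged is not None and len(merged) >= 10:
        merged["group"] = merged["participant_id"].map(group_map)
        if covariates is not None:
            merged = merged.join(covariates, on="participant_id")
        all_feats = [f"{f}_t{t}" for t in usable for f in retained[t]]
        try:
            scores, rule = _model_scores(merged, with_covariates(all_feats), config)
            result = roc_evaluate(scores, merged["group"].to_numpy(), rule)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("evaluate all timescales", str(exc)) from exc
        eval_rows.append(
            _evaluation_row("all_timescales", None, all_feats, result, len(merged))
        )

    # ---- single-feature models and cutoffs at the focal timescale -----------
    t_single = config.single_feature_timescale
    single_rows, cutoff_rows = [], []
    if t_single in usable:
        frame = samples[t_single]
        labels = frame["group"].to_numpy()
        for feature in retained[t_single]:
            try:
                scores, rule = _model_scores(frame, [feature], config)
                result = roc_evaluate(scores, labels, rule)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(
                    f"evaluate single {feature}", str(exc)
                ) from exc
            single_rows.append(
                _evaluation_row(feature, t_single, [feature], result, len(frame))
            )
        for feature in config.cutoff_features:
            if feature not in frame.columns:
                continue
            result = roc_evaluate(
                frame[feature].to_numpy(dtype=float), labels, "youden"
            )
            cutoff_rows.append(
                {
                    "feature": feature,
                    "t": t_single,
                    "cutoff": result.youden_cutoff,
                    "sensitivity": result.sensitivity,
                    "specificity": result.specificity,
                    "youden_index": result.youden_index,
                    "auc": result.auc,
                }
            )

    provenance = {
        "package": "noctivitals",
        "version": __version__,
        "seed": sim.seed,
        "mode": config.mode,
        "config_hash": _config_hash(config),
    }
    return StudyReport(
        evaluation=pd.DataFrame(eval_rows),
        single_features=pd.DataFrame(single_rows),
        cutoffs=pd.DataFrame(cutoff_rows),
        screening=pd.DataFrame(screen_rows),
        qc_summary=qc_summary,
        sample_counts=sample_counts,
        provenance=provenance,
        nightly_features=nights,
        qc_decisions=decisions,
        samples=samples,
    )
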