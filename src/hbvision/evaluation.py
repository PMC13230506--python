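"""Patient-grouped cross-validation and the full metric suite.

Folds are assigned at the patient-ID level so that every visit, image and
derived sample of a patient lands in exactly one fold.  Per-image predictions
are aggregated to a single value per (patient, visit) entry using the median,
inside validation folds only.  Metrics are reported both as means over the
validation folds and pooled over all validation entries; fold-level values
are persisted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chromatic_features import RankDeficientError, fit_pca, transform
from .corridor_decision import LABEL_ORDER, CorridorLabel, hb_to_corridor
from .predictors import GbmParams, fit_classifier, fit_gbm, fit_ridge, predict

__all__ = [
    "FoldPlan",
    "make_grouped_folds",
    "aggregate_predictions",
    "regression_metrics",
    "corridor_confusion",
    "type_error_rates",
    "f1_scores",
    "EvaluationReport",
    "run_grouped_cv",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every patient ID to exactly one of ``k`` folds."""

    k: int
    assignment: Mapping[str, int]
    seed: int

    def patients_in_fold(self, fold: int) -> set:
        return {p for p, f in self.assignment.items() if f == fold}


def make_grouped_folds(patient_ids: Iterable, k: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffle the distinct patient IDs by ``seed`` and deal them round-robin.

    Fold sizes differ by at most one patient, and no patient straddles folds.

    Raises
    ------
    ValueError
        If fewer than ``k`` distinct patients are available.
    """
    unique = sorted(set(patient_ids), key=str)
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct patients, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {unique[idx]: i % k for i, idx in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def aggregate_predictions(per_image_preds: Sequence[float]) -> float:
    """Median of the per-image predictions for one (patient, visit) entry.

    Even counts use the mean of the two central values (numpy convention).
    """
    preds = np.asarray(per_image_preds, dtype=float)
    if preds.size == 0:
        raise ValueError("cannot aggregate an empty prediction list")
    return float(np.median(preds))


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> dict:
    """Residual standard deviation (ddof=1), MSE and R² of ``y_pred`` vs ``y_true``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: y_true is constant")
    residuals = y_pred - y_true
    mse = float(np.mean(residuals**2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot
    residual_sd = float(np.std(residuals, ddof=1))
    return {"residual_sd": residual_sd, "mse": mse, "r2": r2}


def _as_labels(labels: Sequence) -> list[CorridorLabel]:
    return [
        lab if isinstance(lab, CorridorLabel) else CorridorLabel.from_string(lab)
        for lab in labels
    ]


def corridor_confusion(
    true_corridors: Sequence, pred_corridors: Sequence
) -> dict:
    """3x3 confusion matrix (rows = true, cols = predicted, order Red/Yellow/Green).

    Also returns per-corridor accuracy (diagonal / row sum, NaN for empty
    rows), the diagonal sum and the total count.
    """
    t = _as_labels(true_corridors)
    p = _as_labels(pred_corridors)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences must have equal length")
    index = {label: i for i, label in enumerate(LABEL_ORDER)}
    confusion = np.zeros((3, 3), dtype=int)
    for ti, pi in zip(t, p):
        confusion[index[ti], index[pi]] += 1
    row_sums = confusion.sum(axis=1)
    per_class = {}
    for label in LABEL_ORDER:
        i = index[label]
        per_class[label.value] = (
            float(confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        )
    return {
        "confusion": confusion,
        "per_class_accuracy": per_class,
        "total_correct": int(np.trace(confusion)),
        "total": int(confusion.sum()),
    }


def type_error_rates(
    measured_hb: Sequence[float], predicted_hb: Sequence[float]
) -> dict:
    """Type-1 and per-corridor Type-2 error rates from paired Hb values.

    type1 = #(pred Green and true Red) / #(true Red);
    type2[c] = #(true c and pred strictly less severe than c) / #(true c).
    Empty denominators yield ``None`` (rate undefined, not zero).
    Corridors come from the fixed clinical cut-offs.
    """
    measured = np.asarray(measured_hb, dtype=float)
    predicted = np.asarray(predicted_hb, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted Hb must have equal length")
    t = [hb_to_corridor(v) for v in measured]
    p = [hb_to_corridor(v) for v in predicted]

    n_red = sum(1 for lab in t if lab is CorridorLabel.RED)
    if n_red:
        n_t1 = sum(
            1
            for ti, pi in zip(t, p)
            if ti is CorridorLabel.RED and pi is CorridorLabel.GREEN
        )
        type1 = n_t1 / n_red
    else:
        type1 = None

    type2: dict[str, Optional[float]] = {}
    for label in LABEL_ORDER:
        n_c = sum(1 for lab in t if lab is label)
        if n_c == 0:
            type2[label.value] = None
            continue
        n_less = sum(
            1
            for ti, pi in zip(t, p)
            if ti is label and pi.severity < label.severity
        )
        type2[label.value] = n_less / n_c
    return {"type1": type1, "type2": type2}


def f1_scores(true_corridors: Sequence, pred_corridors: Sequence) -> dict:
    """Macro and support-weighted F1 over corridor labels.

    Per-class F1 = 2PR/(P+R), defined as 0 when P+R = 0.  Classes absent
    from both the true and predicted sequences are excluded from the
    averages.
    """
    t = _as_labels(true_corridors)
    p = _as_labels(pred_corridors)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences must have equal length")
    per_class: dict[str, float] = {}
    supports: dict[str, int] = {}
    for label in LABEL_ORDER:
        support = sum(1 for lab in t if lab is label)
        n_pred = sum(1 for lab in p if lab is label)
        if support == 0 and n_pred == 0:
            continue
        tp = sum(1 for ti, pi in zip(t, p) if ti is label and pi is label)
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / support if support else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[label.value] = f1
        supports[label.value] = support
    if not per_class:
        return {"f1_macro": float("nan"), "f1_weighted": float("nan"), "per_class": {}}
    f1_macro = float(np.mean(list(per_class.values())))
    total_support = sum(supports.values())
    if total_support:
        f1_weighted = float(
            sum(per_class[c] * supports[c] for c in per_class) / total_support
        )
    else:
        f1_weighted = f1_macro
    return {"f1_macro": f1_macro, "f1_weighted": f1_weighted, "per_class": per_class}


# ---------------------------------------------------------------------------
# Cross-validation orchestration
# ---------------------------------------------------------------------------

_MODALITIES = ("eyelid", "fingernail")


@dataclass
class EvaluationReport:
    """Per-fold and pooled metrics for one cross-validated pipeline run."""

    task: str
    modality: str
    family: str
    k: int
    seed: int
    n_entries: int
    fold_metrics: list = field(default_factory=list)
    mean_over_folds: dict = field(default_factory=dict)
    pooled: dict = field(default_factory=dict)
    confusion: Optional[np.ndarray] = None
    per_class_accuracy: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    type_errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "modality": self.modality,
            "family": self.family,
            "k": self.k,
            "seed": self.seed,
            "n_entries": self.n_entries,
            "fold_metrics": self.fold_metrics,
            "mean_over_folds": self.mean_over_folds,
            "pooled": self.pooled,
            "per_class_accuracy": self.per_class_accuracy,
            "f1": self.f1,
            "type_errors": self.type_errors,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
        return out


def _hist_columns(features: pd.DataFrame) -> list[str]:
    cols = [c for c in features.columns if c.startswith("h") and c[1:].isdigit()]
    if not cols:
        raise ValueError("feature table has no histogram columns (h00, h01, ...)")
    return sorted(cols, key=lambda c: int(c[1:]))


def _metadata_matrix(rows: pd.DataFrame, age_mean: float, age_sd: float) -> np.ndarray:
    age = (rows["age"].to_numpy(dtype=float) - age_mean) / (age_sd if age_sd else 1.0)
    sex = (rows["sex"].astype(str) == "male").to_numpy(dtype=float)
    return np.column_stack([age, sex])


def _fit_pca_capped(X: np.ndarray, n_components: int):
    """Fit PCA, falling back to the achievable component count when the
    training histograms are rank-deficient (narrow synthetic hue spread)."""
    try:
        return fit_pca(X, n_components)
    except RankDeficientError as exc:
        if exc.achievable < 1:
            raise
        return fit_pca(X, exc.achievable)


def _severity_median(labels: Sequence[CorridorLabel]) -> CorridorLabel:
    """Ordinal median of severity codes; half-ties round toward more severe."""
    codes = np.sort([lab.severity for lab in labels])
    med = float(np.median(codes))
    code = int(np.ceil(med - 1e-9))
    for label in LABEL_ORDER:
        if label.severity == code:
            return label
    raise AssertionError("unreachable")


def run_grouped_cv(
    features: pd.DataFrame,
    entries: pd.DataFrame,
    modality: str = "combined",
    family: str = "gbm",
    task: str = "regression",
    k: int = 10,
    seed: int = 0,
    n_components: int = 8,
    use_metadata: bool = False,
    ridge_penalty: float = 1.0,
    gbm_params: Optional[GbmParams] = None,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Run the full patient-grouped k-fold CV for one modality arm.

    Parameters
    ----------
    features:
        Per-image table with columns ``patient_id``, ``visit_index``,
        ``modality`` and the normalized hue-histogram columns ``h00..hBB``.
    entries:
        Per-(patient, visit) table with ``patient_id``, ``visit_index``,
        ``hb_true`` and (when ``use_metadata``) ``age`` and ``sex``.
    modality:
        ``"eyelid"``, ``"fingernail"`` or ``"combined"``.  Single arms
        predict per image and aggregate by median; the combined arm
        concatenates per-entry median PCA scores of both modalities and
        drops entries missing either one.
    task:
        ``"regression"`` (continuous Hb) or ``"classification"``
        (three-class corridor labels).

    Returns the per-entry prediction table and an :class:`EvaluationReport`.
    PCA is fitted inside each training fold only.  A leakage audit asserts
    empty train/validation patient overlap in every fold.
    """
    if modality not in (*_MODALITIES, "combined"):
        raise ValueError(f"unknown modality arm {modality!r}")
    if family not in ("ridge", "gbm"):
        raise ValueError(f"unknown model family {family!r}")
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")

    hcols = _hist_columns(features)
    arm_modalities = _MODALITIES if modality == "combined" else (modality,)
    feats = features[features["modality"].isin(arm_modalities)].reset_index(drop=True)
    merged = feats.merge(
        entries, on=["patient_id", "visit_index"], how="inner", validate="many_to_one"
    )
    if merged.empty:
        raise ValueError("no feature rows match the entry table")

    plan = make_grouped_folds(merged["patient_id"], k=k, seed=seed)
    gbm_params = gbm_params or GbmParams(seed=seed)

    records: list[dict] = []
    for fold in range(k):
        val_patients = plan.patients_in_fold(fold)
        is_val = merged["patient_id"].isin(val_patients)
        train = merged[~is_val]
        val = merged[is_val]
        # leakage audit: hard assertion on every run
        overlap = set(train["patient_id"]) & set(val["patient_id"])
        assert not overlap, f"patient leakage across folds: {sorted(overlap)[:5]}"
        if val.empty or train.empty:
            continue

        age_mean = age_sd = 0.0
        if use_metadata:
            age_mean = float(train["age"].mean())
            age_sd = float(train["age"].std(ddof=0))

        if modality != "combined":
            pca = _fit_pca_capped(train[hcols].to_numpy(dtype=float), n_components)

            def image_design(rows: pd.DataFrame) -> np.ndarray:
                scores = transform(rows[hcols].to_numpy(dtype=float), pca)
                if use_metadata:
                    scores = np.hstack([scores, _metadata_matrix(rows, age_mean, age_sd)])
                return scores

            X_train, train_rows = image_design(train), train
            X_val, val_rows = image_design(val), val
        else:
            pcas = {}
            for m in _MODALITIES:
                sub = train[train["modality"] == m]
                if len(sub) <= n_components:
                    raise ValueError(
                        f"combined arm: not enough {m} training images for PCA"
                    )
                pcas[m] = _fit_pca_capped(sub[hcols].to_numpy(dtype=float), n_components)

            def entry_design(rows: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
                feats_by_entry = {}
                for (pid, visit), grp in rows.groupby(["patient_id", "visit_index"]):
                    per_mod = {}
                    for m in _MODALITIES:
                        sub = grp[grp["modality"] == m]
                        if sub.empty:
                            break
                        scores = transform(sub[hcols].to_numpy(dtype=float), pcas[m])
                        per_mod[m] = np.median(scores, axis=0)
                    if len(per_mod) == len(_MODALITIES):
                        feats_by_entry[(pid, visit)] = np.concatenate(
                            [per_mod[m] for m in _MODALITIES]
                        )
                if not feats_by_entry:
                    width = sum(p.n_components for p in pcas.values())
                    return np.empty((0, width)), rows.iloc[:0]
                keys = list(feats_by_entry)
                X = np.vstack([feats_by_entry[key] for key in keys])
                entry_rows = (
                    rows.drop_duplicates(["patient_id", "visit_index"])
                    .set_index(["patient_id", "visit_index"])
                    .loc[keys]
                    .reset_index()
                )
                if use_metadata:
                    X = np.hstack([X, _metadata_matrix(entry_rows, age_mean, age_sd)])
                return X, entry_rows

            X_train, train_rows = entry_design(train)
            X_val, val_rows = entry_design(val)
            if len(val_rows) == 0:
                continue

        y_train = train_rows["hb_true"].to_numpy(dtype=float)

        if task == "regression":
            if family == "ridge":
                model = fit_ridge(X_train, y_train, penalty=ridge_penalty)
            else:
                model = fit_gbm(X_train, y_train, params=gbm_params)
            raw_pred = predict(model, X_val)
            val_pred = pd.DataFrame(
                {
                    "patient_id": val_rows["patient_id"].to_numpy(),
                    "visit_index": val_rows["visit_index"].to_numpy(),
                    "hb_true": val_rows["hb_true"].to_numpy(dtype=float),
                    "pred": raw_pred,
                }
            )
            for (pid, visit), grp in val_pred.groupby(["patient_id", "visit_index"]):
                records.append(
                    {
                        "patient_id": pid,
                        "visit_index": visit,
                        "fold": fold,
                        "hb_true": float(grp["hb_true"].iloc[0]),
                        "hb_pred": aggregate_predictions(grp["pred"].to_list()),
                    }
                )
        else:
            labels_train = [hb_to_corridor(v) for v in y_train]
            clf = fit_classifier(
                X_train,
                labels_train,
                family=family,
                ridge_penalty=ridge_penalty,
                gbm_params=gbm_params,
            )
            raw_labels = predict(clf, X_val)
            val_pred = pd.DataFrame(
                {
                    "patient_id": val_rows["patient_id"].to_numpy(),
                    "visit_index": val_rows["visit_index"].to_numpy(),
                    "hb_true": val_rows["hb_true"].to_numpy(dtype=float),
                }
            )
            val_pred["pred_label"] = raw_labels
            for (pid, visit), grp in val_pred.groupby(["patient_id", "visit_index"]):
                records.append(
                    {
                        "patient_id": pid,
                        "visit_index": visit,
                        "fold": fold,
                        "hb_true": float(grp["hb_true"].iloc[0]),
                        "pred_label": _severity_median(
                            list(grp["pred_label"])
                        ).value,
                    }
                )

    predictions = pd.DataFrame.from_records(records)
    report = EvaluationReport(
        task=task,
        modality=modality,
        family=family,
        k=k,
        seed=seed,
        n_entries=len(predictions),
    )
    if predictions.empty:
        return predictions, report

    if task == "regression":
        for fold, grp in predictions.groupby("fold"):
            try:
                metrics = regression_metrics(grp["hb_true"], grp["hb_pred"])
            except ValueError:
                metrics = {"residual_sd": None, "mse": None, "r2": None}
            metrics["fold"] = int(fold)
            metrics["n_entries"] = len(grp)
            report.fold_metrics.append(metrics)
        valid = [m for m in report.fold_metrics if m["r2"] is not None]
        if valid:
            report.mean_over_folds = {
                key: float(np.mean([m[key] for m in valid]))
                for key in ("residual_sd", "mse", "r2")
            }
        report.pooled = regression_metrics(predictions["hb_true"], predictions["hb_pred"])
        true_labels = [hb_to_corridor(v) for v in predictions["hb_true"]]
        pred_labels = [hb_to_corridor(v) for v in predictions["hb_pred"]]
        report.type_errors = type_error_rates(
            predictions["hb_true"], predictions["hb_pred"]
        )
    else:
        true_labels = [hb_to_corridor(v) for v in predictions["hb_true"]]
        pred_labels = _as_labels(predictions["pred_label"])
        for fold, grp in predictions.groupby("fold"):
            t = [hb_to_corridor(v) for v in grp["hb_true"]]
            p = _as_labels(grp["pred_label"])
            metrics = f1_scores(t, p)
            report.fold_metrics.append(
                {
                    "fold": int(fold),
                    "n_entries": len(grp),
                    "f1_macro": metrics["f1_macro"],
                    "f1_weighted": metrics["f1_weighted"],
                }
            )
        report.mean_over_folds = {
            key: float(np.mean([m[key] for m in report.fold_metrics]))
            for key in ("f1_macro", "f1_weighted")
        }

    summary = corridor_confusion(true_labels, pred_labels)
    report.confusion = summary["confusion"]
    report.per_class_accuracy = summary["per_class_accuracy"]
    report.f1 = f1_scores(true_labels, pred_labels)
    return predictions, report
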