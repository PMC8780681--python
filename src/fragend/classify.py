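"""Cancer-vs-healthy classification from fragment-end features.

A support vector machine on standardized features (per-region
fragmentation scores + 16 end-motif frequencies). Hyperparameters are
selected by repeated stratified cross-validation (default 10 repeats x
10 folds) maximizing the mean out-of-fold ROC AUC; standardization is
re-fit inside every fold so no test information leaks into the scaler.
The selected model is refit on all training data and its decision values
are calibrated to probabilities with a Platt sigmoid fitted on
out-of-fold decision values, yielding a cancer score in [0, 1] per
sample, thresholded at 0.5 by default.

Ties between grid points resolve toward the simpler model: linear before
RBF, then smaller C, then smaller gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from fragend.fragmentomics import PeakPair

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

POSITIVE_LABEL = "cancer"
DEFAULT_CUTOFF = 0.5

#: Hyperparameter grid in tie-break (simplicity) order.
DEFAULT_GRID: list[dict] = [
    {"kernel": "linear", "C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)
] + [
    {"kernel": "rbf", "C": c, "gamma_mult": g}
    for c in (0.01, 0.1, 1.0, 10.0, 100.0)
    for g in (0.1, 1.0, 10.0)
]


def make_split(
    metadata: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign samples to train/test, stratified by class label.

    Returns a copy of ``metadata`` with a ``split`` column. If the input
    already carries a ``split`` column with train/test values it is
    honored unchanged. Raises if either side would lack a class.
    """
    out = metadata.copy()
    if "split" in out.columns and set(out["split"].unique()) <= {"train", "test"}:
        splits = out["split"]
    else:
        if out["label"].nunique() < 2:
            raise ValueError("need both classes to split")
        idx_train, idx_test = train_test_split(
            np.arange(len(out)),
            test_size=test_fraction,
            random_state=seed,
            stratify=out["label"],
        )
        splits = pd.Series("train", index=out.index)
        splits.iloc[idx_test] = "test"
        out["split"] = splits
    for side in ("train", "test"):
        classes = out.loc[out["split"] == side, "label"].nunique()
        if classes < 2:
            raise ValueError(f"{side} split lacks one of the classes")
    return out


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    ``labels`` are truthy for the positive class; ties in ``scores``
    contribute 1/2. Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc undefined: only one class present")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels):
    """ROC curve points (fpr, tpr, thresholds) for plotting against the
    chance diagonal."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("roc_curve undefined: only one class present")
    return _sk_roc_curve(y.astype(int), np.asarray(scores, dtype=float))


def _make_svc(params: dict, x: np.ndarray) -> SVC:
    kwargs = {"kernel": params["kernel"], "C": params["C"]}
    if params["kernel"] == "rbf":
        var = float(x.var())
        scale = 1.0 / (x.shape[1] * var) if var > 0 else 1.0
        kwargs["gamma"] = params.get("gamma_mult", 1.0) * scale
    return SVC(**kwargs)


@dataclass
class TrainedModel:
    """Fitted scaler + SVM + Platt calibration + frozen peak definitions."""

    feature_names: list[str]
    scaler: StandardScaler
    svc: SVC
    calibrator: LogisticRegression
    peaks: dict[str, PeakPair] = field(default_factory=dict)
    cv_record: dict = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF
    format_version: int = MODEL_FORMAT_VERSION

    def _check_columns(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = sorted(set(self.feature_names) - set(features.columns))
        extra = sorted(set(features.columns) - set(self.feature_names))
        if missing or extra:
            raise ValueError(
                f"feature columns do not match the trained model; "
                f"missing={missing} unexpected={extra}"
            )
        return features[self.feature_names]

    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        x = self.scaler.transform(self._check_columns(features).to_numpy(dtype=float))
        return self.svc.decision_function(x)

    def cancer_scores(self, features: pd.DataFrame) -> np.ndarray:
        d = self.decision_values(features).reshape(-1, 1)
        return self.calibrator.predict_proba(d)[:, 1]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        if model.format_version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format {model.format_version} != supported {MODEL_FORMAT_VERSION}"
            )
        return model


def tune_and_train(
    features: pd.DataFrame,
    labels,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    grid: list[dict] | None = None,
    peaks: dict[str, PeakPair] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> TrainedModel:
    """Grid-search an SVM under repeated stratified CV and refit.

    For each grid point the out-of-fold AUC is computed in every one of
    ``repeats x folds`` folds (scaler re-fit per fold); the grid point
    with the highest mean AUC wins, exact ties going to the earlier
    (simpler) grid entry. Folds whose validation side is single-class
    are skipped with a warning and counted in the CV record. The winner
    is refit on all training data with Platt calibration fitted on
    out-of-fold decision values.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    x = features.to_numpy(dtype=float)
    lab = pd.Series(list(labels))
    y = (
        lab.eq(POSITIVE_LABEL).to_numpy(dtype=int)
        if lab.dtype == object
        else lab.to_numpy(dtype=int)
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    prepared = []
    skipped = 0
    for tr, va in rskf.split(x, y):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            skipped += 1
            logger.warning("skipping degenerate single-class CV fold")
            continue
        scaler = StandardScaler().fit(x[tr])
        prepared.append((scaler.transform(x[tr]), y[tr], scaler.transform(x[va]), y[va]))
    if not prepared:
        raise ValueError("no usable CV folds")

    fold_aucs = np.empty((len(grid), len(prepared)))
    for gi, params in enumerate(grid):
        for fi, (xtr, ytr, xva, yva) in enumerate(prepared):
            svc = _make_svc(params, xtr).fit(xtr, ytr)
            fold_aucs[gi, fi] = roc_auc(svc.decision_function(xva), yva)
    mean_aucs = fold_aucs.mean(axis=1)
    best = int(np.argmax(mean_aucs))  # first max: simpler model wins ties
    best_params = grid[best]
    best_fold_aucs = fold_aucs[best]

    per_repeat = [
        float(np.mean(chunk))
        for chunk in np.array_split(best_fold_aucs, repeats)
        if len(chunk)
    ]

    # Platt calibration on out-of-fold decision values of the winner
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for tr, va in skf.split(x, y):
        scaler = StandardScaler().fit(x[tr])
        svc = _make_svc(params=best_params, x=scaler.transform(x[tr])).fit(
            scaler.transform(x[tr]), y[tr]
        )
        oof[va] = svc.decision_function(scaler.transform(x[va]))
    calibrator = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    calibrator.fit(oof.reshape(-1, 1), y)

    final_scaler = StandardScaler().fit(x)
    xs = final_scaler.transform(x)
    final_svc = _make_svc(best_params, xs).fit(xs, y)

    cv_record = {
        "grid_size": len(grid),
        "best_params": dict(best_params),
        "cv_mean_auc": float(best_fold_aucs.mean()),
        "cv_sd_auc": float(best_fold_aucs.std(ddof=1)) if len(best_fold_aucs) > 1 else 0.0,
        "n_folds": int(len(prepared)),
        "skipped_folds": int(skipped),
        "per_repeat_mean_auc": per_repeat,
    }
    logger.info(
        "selected %s: CV mean AUC %.3f (sd %.3f, n=%d)",
        best_params, cv_record["cv_mean_auc"], cv_record["cv_sd_auc"], len(prepared),
    )
    return TrainedModel(
        feature_names=list(features.columns),
        scaler=final_scaler,
        svc=final_svc,
        calibrator=calibrator,
        peaks=peaks or {},
        cv_record=cv_record,
        cutoff=cutoff,
    )


def predict(model: TrainedModel, features: pd.DataFrame, cutoff: float | None = None) -> pd.DataFrame:
    """Per-sample cancer scores and predicted classes.

    The cancer score is the calibrated probability that the sample comes
    from a cancer patient; predicted class is ``cancer`` when the score
    reaches the decision cutoff (default the model's stored 0.5).
    """
    if cutoff is None:
        cutoff = model.cutoff
    scores = model.cancer_scores(features)
    return pd.DataFrame(
        {
            "sample_id": features.index.astype(str),
            "cancer_score": scores,
            "predicted_class": np.where(scores >= cutoff, POSITIVE_LABEL, "healthy"),
        }
    ).reset_index(drop=True)


EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


def _stratum_metrics(scores: np.ndarray, y: np.ndarray, cutoff: float) -> dict:
    n = int(len(y))
    if n == 0 or len(np.unique(y)) < 2:
        return {"auc": None, "accuracy": None, "n": n}
    pred = (scores >= cutoff).astype(int)
    return {
        "auc": roc_auc(scores, y),
        "accuracy": float((pred == y).mean()),
        "n": n,
    }


def evaluate_stratified(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Overall and stratified performance of per-sample cancer scores.

    ``scores`` is the output of :func:`predict`; ``metadata`` must carry
    sample_id, label and (for stratification) stage and cancer_type.
    Strata: early-stage (I, II) and late-stage (III, IV) cancer, and
    each cancer type — each evaluated against all healthy samples as the
    negative class. Also reports per-clinical-group score medians and
    sds. Empty strata come back with ``auc: None`` and their n.
    """
    merged = scores.merge(metadata, on="sample_id", how="inner", validate="1:1")
    if len(merged) != len(scores):
        raise ValueError("metadata missing for some scored samples")
    y = merged["label"].eq(POSITIVE_LABEL).to_numpy(dtype=int)
    s = merged["cancer_score"].to_numpy()
    healthy = y == 0

    report: dict = {"overall": _stratum_metrics(s, y, cutoff), "strata": {}, "score_summaries": {}}

    def stratum(name: str, cancer_mask: np.ndarray) -> None:
        mask = healthy | cancer_mask
        report["strata"][name] = _stratum_metrics(s[mask], y[mask], cutoff)
        report["strata"][name]["n_cancer"] = int(cancer_mask.sum())

    cancer = ~healthy
    stage = merged["stage"].fillna("").to_numpy(dtype=object)
    ctype = merged["cancer_type"].fillna("").to_numpy(dtype=object)
    stratum("stage_early", cancer & np.isin(stage, EARLY_STAGES))
    stratum("stage_late", cancer & np.isin(stage, LATE_STAGES))
    for t in sorted({t for t in ctype[cancer] if t}):
        stratum(f"type_{t}", cancer & (ctype == t))

    groups = {"healthy": healthy}
    for st in ("I", "II", "III", "IV"):
        groups[f"stage_{st}"] = cancer & (stage == st)
    for name, mask in groups.items():
        vals = s[mask]
        report["score_summaries"][name] = {
            "median": float(np.median(vals)) if len(vals) else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            "n": int(mask.sum()),
        }
    return report
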