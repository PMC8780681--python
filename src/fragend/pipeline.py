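"""In-memory end-to-end analysis of a cohort of fragment records.

Convenience wrapper chaining the pipeline stages without file I/O:
train/test split, peak freezing on the training split, feature assembly,
SVM tuning, prediction and stratified evaluation. The CLI provides the
same flow with files between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from fragend import classify, fragmentomics
from fragend.classify import TrainedModel
from fragend.synthetic import CohortConfig, GroundTruth, generate_cohort


@dataclass
class CohortAnalysis:
    """Everything produced by one end-to-end run."""

    metadata: pd.DataFrame          # with split column
    features: pd.DataFrame
    model: TrainedModel
    test_scores: pd.DataFrame
    report: dict
    truth: GroundTruth | None = None

    @property
    def cv_mean_auc(self) -> float:
        return self.model.cv_record["cv_mean_auc"]

    @property
    def test_auc(self) -> float:
        return self.report["overall"]["auc"]


def analyze_records(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
    test_fraction: float = 0.3,
    repeats: int = 10,
    folds: int = 10,
    grid: list[dict] | None = None,
    eps: float = fragmentomics.DEFAULT_EPS,
    smooth_halfwidth: int = fragmentomics.DEFAULT_SMOOTH_HALFWIDTH,
    window_halfwidth: int = fragmentomics.DEFAULT_WINDOW_HALFWIDTH,
) -> CohortAnalysis:
    """Split, freeze peaks on train, featurize, train, score the test split."""
    metadata = classify.make_split(metadata, test_fraction=test_fraction, seed=seed)
    train_ids = set(metadata.loc[metadata["split"] == "train", "sample_id"])
    region_ids = sorted(records["region_id"].unique())
    peaks = fragmentomics.detect_all_peaks(
        records[records["sample_id"].isin(train_ids)],
        region_ids,
        smooth_halfwidth=smooth_halfwidth,
        window_halfwidth=window_halfwidth,
    )
    features = fragmentomics.assemble_features(
        records, peaks, eps=eps, sample_ids=sorted(metadata["sample_id"])
    )
    train_meta = metadata[metadata["split"] == "train"]
    model = classify.tune_and_train(
        features.loc[train_meta["sample_id"]],
        train_meta["label"],
        repeats=repeats,
        folds=folds,
        seed=seed,
        grid=grid,
        peaks=peaks,
    )
    test_meta = metadata[metadata["split"] == "test"]
    test_scores = classify.predict(model, features.loc[test_meta["sample_id"]])
    report = classify.evaluate_stratified(test_scores, test_meta)
    return CohortAnalysis(
        metadata=metadata,
        features=features,
        model=model,
        test_scores=test_scores,
        report=report,
    )


def analyze_cohort(config: CohortConfig, **kwargs) -> CohortAnalysis:
    """Simulate a cohort from ``config`` and analyze it end to end.

    The split/CV seed defaults to the cohort seed; override via ``seed=``.
    """
    kwargs.setdefault("seed", config.seed)
    records, truth, metadata = generate_cohort(config)
    analysis = analyze_records(records, metadata, **kwargs)
    analysis.truth = truth
    return analysis
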