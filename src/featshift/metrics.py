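"""Classifier metrics and distributional comparisons.

Metrics are pooled over all masked-in residues of the evaluation set (micro
over residues) and macro-averaged over the two classes for F1, precision and
recall.  AUROC is threshold-free; binary metrics use the 0.5 decision
threshold recorded on each prediction profile.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, matthews_corrcoef,
                             precision_recall_fscore_support, roc_auc_score)

from .annotations import LabelTrack
from .model import PredictionProfile

__all__ = [
    "MetricReport",
    "DistributionComparison",
    "compute_metrics",
    "paired_wilcoxon",
    "compare_score_distributions",
    "write_metric_report",
]


@dataclasses.dataclass(frozen=True)
class MetricReport:
    feature: str
    model: str
    auroc: float            # NaN when truth is single-class (undefined)
    f1_macro: float
    precision_macro: float
    recall_macro: float
    mcc: float
    accuracy: float
    n_residues: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class DistributionComparison:
    """Two-sample KS comparison of residue score distributions.

    The effect size is the KS statistic itself (the maximum empirical CDF
    gap); a comparison is flagged significant when p ≤ alpha and the effect
    size reaches ``min_effect``.
    """

    feature: str
    score_name: str
    ks_statistic: float
    p_value: float
    effect_size: float
    significant: bool


def _pool(truth: Sequence[LabelTrack],
          predictions: Sequence[PredictionProfile]):
    by_key = {(p.protein_id, p.feature): p for p in predictions}
    y_true, y_prob, y_pred = [], [], []
    for track in truth:
        prof = by_key.get((track.protein_id, track.feature))
        if prof is None:
            raise ValueError(
                f"no prediction for {track.protein_id}/{track.feature}"
            )
        if prof.probabilities.shape[0] != track.length:
            raise ValueError(
                f"{track.protein_id}: prediction length mismatch"
            )
        keep = track.mask == 1
        y_true.append(track.labels[keep])
        y_prob.append(prof.probabilities[keep])
        y_pred.append(prof.labels_pred[keep])
    return (np.concatenate(y_true), np.concatenate(y_prob),
            np.concatenate(y_pred))


def compute_metrics(truth: Sequence[LabelTrack],
                    predictions: Sequence[PredictionProfile],
                    model: str = "") -> MetricReport:
    """Pooled per-residue metrics over matched truth/prediction sets."""
    y_true, y_prob, y_pred = _pool(truth, predictions)
    if y_true.size == 0:
        raise ValueError("no masked-in residues to evaluate")
    feature = truth[0].feature
    if y_true.min() == y_true.max():
        warnings.warn("single-class truth: AUROC is undefined")
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, y_prob))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="macro", zero_division=0
    )
    return MetricReport(
        feature=feature,
        model=model,
        auroc=auroc,
        f1_macro=float(f1),
        precision_macro=float(precision),
        recall_macro=float(recall),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        accuracy=float(accuracy_score(y_true, y_pred)),
        n_residues=int(y_true.size),
    )


def paired_wilcoxon(ft_scores: Sequence[float],
                    fe_scores: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on per-feature score pairs.

    Zero differences are dropped (the classic signed-rank rule).  Returns
    ``(statistic, p_value)``; all-zero differences give p = 1 with a warning.
    """
    ft = np.asarray(ft_scores, dtype=float)
    fe = np.asarray(fe_scores, dtype=float)
    if ft.shape != fe.shape or ft.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and equal-length")
    if np.all(ft == fe):
        warnings.warn("all paired differences are zero; p-value is 1")
        return 0.0, 1.0
    res = stats.wilcoxon(ft, fe, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_score_distributions(scores_labeled: Sequence[float],
                                scores_predicted: Sequence[float],
                                feature: str = "",
                                score_name: str = "",
                                alpha: float = 0.05,
                                min_effect: float = 0.2) -> DistributionComparison:
    """Two-sample Kolmogorov–Smirnov comparison of labeled vs predicted scores."""
    a = np.asarray(scores_labeled, dtype=float)
    b = np.asarray(scores_predicted, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations in each sample")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    ks = float(res.statistic)
    p = float(res.pvalue)
    return DistributionComparison(
        feature=feature, score_name=score_name,
        ks_statistic=ks, p_value=p, effect_size=ks,
        significant=bool(p <= alpha and ks >= min_effect),
    )


def write_metric_report(reports: Sequence[MetricReport],
                        path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump([r.as_dict() for r in reports], fh, indent=2)
        return
    fields = ["feature", "model", "auroc", "f1_macro", "precision_macro",
              "recall_macro", "mcc", "accuracy", "n_residues"]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for r in reports:
            d = r.as_dict()
            fh.write("\t".join(str(d[f]) for f in fields) + "\n")
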