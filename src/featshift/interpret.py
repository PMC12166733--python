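"""Mechanistic missense-variant interpretation via differential feature profiles.

The workflow: run the reference and the alternate (single-substitution)
protein sequence through the per-feature classifiers, take the positionwise
difference of predicted probabilities (alt − ref), and call a feature *gain*
where the predicted label flips 0→1 and a *loss* where it flips 1→0.  An
optional threshold on |delta| keeps only changes of at least that magnitude;
threshold 0 reproduces pure label-flip calling.  Changes are reported along
the whole protein, not just at the variant site — substitutions can perturb
predictions at distant positions.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (ProteinRecord, VariantRecord, apply_variant,
                          format_protein_variant)
from .model import Checkpoint

__all__ = [
    "DiffProfile",
    "FeatureChangeCall",
    "diff_profile",
    "call_changes",
    "sensitivity_sweep",
    "summarize_cohort",
    "calls_to_frame",
    "write_call_tsv",
    "plot_feature_changes",
]


@dataclasses.dataclass
class DiffProfile:
    """Per-residue probability deltas for one variant and one feature."""

    variant: VariantRecord
    feature: str
    delta: np.ndarray          # p_alt - p_ref, each in [-1, 1]
    ref_labels: np.ndarray
    alt_labels: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.ref_labels = np.asarray(self.ref_labels, dtype=np.int8)
        self.alt_labels = np.asarray(self.alt_labels, dtype=np.int8)
        if not (self.delta.shape == self.ref_labels.shape == self.alt_labels.shape):
            raise ValueError("delta and label vectors must share one length")
        if np.any(np.abs(self.delta) > 1 + 1e-12):
            raise ValueError("|delta| must not exceed 1")


@dataclasses.dataclass(frozen=True)
class FeatureChangeCall:
    """One called feature gain or loss at one residue position (1-based)."""

    variant: VariantRecord
    feature: str
    position: int
    direction: str             # "gain" (0→1) or "loss" (1→0)
    magnitude: float           # |delta| at the position


def diff_profile(ref: ProteinRecord, variant: VariantRecord,
                 checkpoints: Mapping[str, Checkpoint],
                 features: Sequence[str] | None = None) -> list[DiffProfile]:
    """Differential ref-vs-alt probability profiles, one per feature.

    ``checkpoints`` maps feature name → trained checkpoint.  Requesting a
    feature with no checkpoint is an error listing every missing feature.
    """
    wanted = list(features) if features is not None else sorted(checkpoints)
    missing = [f for f in wanted if f not in checkpoints]
    if missing:
        raise ValueError(f"no checkpoint for features: {missing}")
    alt = apply_variant(ref, variant)
    profiles: list[DiffProfile] = []
    for feature in wanted:
        ckpt = checkpoints[feature]
        (p_ref,) = ckpt.predict([ref])
        (p_alt,) = ckpt.predict([alt])
        profiles.append(DiffProfile(
            variant=variant, feature=feature,
            delta=p_alt.probabilities - p_ref.probabilities,
            ref_labels=p_ref.labels_pred, alt_labels=p_alt.labels_pred,
        ))
    return profiles


def call_changes(diffs: Sequence[DiffProfile],
                 threshold: float = 0.0) -> list[FeatureChangeCall]:
    """Call gains/losses: label flip AND |delta| ≥ threshold.

    Threshold 0 (the default) reproduces pure label-flip calling; larger
    thresholds keep only changes with a probability shift of at least that
    magnitude, trading sensitivity for specificity.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    calls: list[FeatureChangeCall] = []
    for diff in diffs:
        flips = np.nonzero(diff.ref_labels != diff.alt_labels)[0]
        for i in flips:
            magnitude = abs(float(diff.delta[i]))
            if magnitude < threshold:
                continue
            direction = "gain" if diff.alt_labels[i] == 1 else "loss"
            calls.append(FeatureChangeCall(
                variant=diff.variant, feature=diff.feature,
                position=int(i) + 1, direction=direction, magnitude=magnitude,
            ))
    return calls


def sensitivity_sweep(diffs: Sequence[DiffProfile],
                      thresholds: Sequence[float] = tuple(
                          np.round(np.arange(0.1, 0.95, 0.1), 1))
                      ) -> pd.DataFrame:
    """Call counts across a threshold sweep (counts non-increasing upward)."""
    thresholds = list(thresholds)
    if any(t2 < t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    rows = [{"threshold": t, "n_calls": len(call_changes(diffs, t))}
            for t in thresholds]
    return pd.DataFrame(rows)


def summarize_cohort(calls: Sequence[FeatureChangeCall]) -> pd.DataFrame:
    """Per-feature gain/loss counts split by variant class.

    Returns a long-format frame with columns feature, direction, label and
    n_calls; row sums conserve the total call count.
    """
    counter: Counter[tuple[str, str, str]] = Counter()
    for call in calls:
        counter[(call.feature, call.direction, call.variant.label)] += 1
    rows = [
        {"feature": f, "direction": d, "label": lab, "n_calls": n}
        for (f, d, lab), n in sorted(counter.items())
    ]
    return pd.DataFrame(rows, columns=["feature", "direction", "label",
                                       "n_calls"])


def calls_to_frame(calls: Sequence[FeatureChangeCall]) -> pd.DataFrame:
    rows = [{
        "variant": format_protein_variant(c.variant),
        "label": c.variant.label,
        "feature": c.feature,
        "position": c.position,
        "direction": c.direction,
        "magnitude": c.magnitude,
    } for c in calls]
    return pd.DataFrame(rows, columns=["variant", "label", "feature",
                                       "position", "direction", "magnitude"])


def write_call_tsv(calls: Sequence[FeatureChangeCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def plot_feature_changes(calls: Sequence[FeatureChangeCall], ax=None):
    """Dot plot of called feature changes along the protein.

    One dot per call: x = residue position, y = feature, marker by direction
    (gain ▲ / loss ▼), size by |delta|.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    features = sorted({c.feature for c in calls})
    y_index = {f: i for i, f in enumerate(features)}
    for direction, marker, color in (("gain", "^", "tab:green"),
                                     ("loss", "v", "tab:red")):
        sel = [c for c in calls if c.direction == direction]
        if not sel:
            continue
        ax.scatter([c.position for c in sel],
                   [y_index[c.feature] for c in sel],
                   s=[20 + 80 * c.magnitude for c in sel],
                   marker=marker, color=color, alpha=0.7, label=direction)
    ax.set_yticks(range(len(features)))
    ax.set_yticklabels(features)
    ax.set_xlabel("residue position")
    ax.legend()
    return ax
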