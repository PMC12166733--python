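"""Per-residue binary feature classifiers: model, training loop and results.

The central object is :class:`ResidueClassifier`, a model built from data in
the statsmodels style: construct it from train/validation proteins and label
tracks plus a backbone, call :meth:`ResidueClassifier.fit`, and receive a
:class:`ResidueClassifierResults` carrying the selected checkpoint, the
per-epoch loss log and evaluation helpers.

Two training modes are supported.  ``frozen_embedding`` trains only the
classification head on fixed backbone embeddings (computed once and cached).
``fine_tune`` additionally trains low-rank adapters inserted at the
query/key/value/output projections of the backbone's attention blocks; all
base backbone weights stay frozen.  In both modes the retained checkpoint is
the epoch with the lowest validation loss.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import LabelTrack, ProteinRecord
from .backbones import (LoRAConfig, LoRALinear, OneHotWindowBackbone,
                        TinyTransformerBackbone, attach_lora, toy_backbone)
from .nn import Adam, Linear, Tensor, dropout, masked_cross_entropy, relu, softmax

__all__ = [
    "HeadConfig",
    "TrainingConfig",
    "PredictionProfile",
    "ClassificationHead",
    "Checkpoint",
    "ResidueClassifier",
    "ResidueClassifierResults",
    "predict",
    "write_prediction_tsv",
]


@dataclasses.dataclass(frozen=True)
class HeadConfig:
    """Classification head: linear → ReLU → dropout → linear → softmax."""

    hidden_size: int = 32
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 3e-4
    epochs: int = 10
    mode: str = "frozen_embedding"          # or "fine_tune"
    seed: int = 0
    batch_size: int = 1
    max_length: int = 1024
    class_weighting: bool = False           # inverse-frequency CE weights

    def __post_init__(self) -> None:
        if self.mode not in {"fine_tune", "frozen_embedding"}:
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.max_length < 1:
            raise ValueError("epochs, batch_size and max_length must be positive")


@dataclasses.dataclass
class PredictionProfile:
    """Per-residue feature-presence probabilities for one protein."""

    protein_id: str
    feature: str
    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def labels_pred(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(np.int8)


class ClassificationHead:
    def __init__(self, d_in: int, config: HeadConfig, rng: np.random.Generator):
        self.config = config
        self.l1 = Linear(d_in, config.hidden_size, rng)
        self.l2 = Linear(config.hidden_size, 2, rng)
        for p in self.parameters():
            p.requires_grad = True

    def logits(self, x: Tensor, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = relu(self.l1(x))
        h = dropout(h, self.config.dropout, rng, training)
        return self.l2(h)

    def parameters(self) -> list[Tensor]:
        return self.l1.parameters() + self.l2.parameters()


def _named_trainable(head: ClassificationHead, backbone) -> dict[str, Tensor]:
    named = {
        "head.l1.W": head.l1.W, "head.l1.b": head.l1.b,
        "head.l2.W": head.l2.W, "head.l2.b": head.l2.b,
    }
    if hasattr(backbone, "blocks"):
        for i, block in enumerate(backbone.blocks):
            for site, layer in block.sites.items():
                if isinstance(layer, LoRALinear):
                    named[f"backbone.block{i}.{site}.A"] = layer.A
                    named[f"backbone.block{i}.{site}.B"] = layer.B
    return named


# ---------------------------------------------------------------------------
# Checkpoint
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Checkpoint:
    """A trained classifier for one feature, self-describing and reloadable."""

    feature: str
    backbone: object
    head: ClassificationHead
    head_config: HeadConfig
    lora_config: LoRAConfig | None
    training_config: TrainingConfig
    best_epoch: int
    val_loss: float

    def predict(self, proteins: Sequence[ProteinRecord],
                overlap: int = 64) -> list[PredictionProfile]:
        return predict(self, proteins, overlap=overlap)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        named = _named_trainable(self.head, self.backbone)
        np.savez(directory / "weights.npz",
                 **{k: v.data for k, v in named.items()})
        manifest = {
            "feature": self.feature,
            "backbone": self.backbone.spec,
            "head_config": dataclasses.asdict(self.head_config),
            "lora_config": (dataclasses.asdict(self.lora_config)
                            if self.lora_config else None),
            "training_config": dataclasses.asdict(self.training_config),
            "best_epoch": self.best_epoch,
            "val_loss": self.val_loss,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @staticmethod
    def load(directory: str | Path) -> "Checkpoint":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        backbone = toy_backbone(manifest["backbone"]["kind"],
                                **manifest["backbone"]["params"])
        lora_config = None
        if manifest["lora_config"] is not None:
            lc = dict(manifest["lora_config"])
            lc["target_sites"] = tuple(lc["target_sites"])
            lora_config = LoRAConfig(**lc)
            backbone = attach_lora(backbone, lora_config,
                                   seed=manifest["training_config"]["seed"])
        head_config = HeadConfig(**manifest["head_config"])
        training_config = TrainingConfig(**manifest["training_config"])
        rng = np.random.default_rng(training_config.seed)
        head = ClassificationHead(backbone.embedding_dim, head_config, rng)
        weights = np.load(directory / "weights.npz")
        for name, tensor in _named_trainable(head, backbone).items():
            tensor.data = np.array(weights[name])
        return Checkpoint(
            feature=manifest["feature"], backbone=backbone, head=head,
            head_config=head_config, lora_config=lora_config,
            training_config=training_config,
            best_epoch=manifest["best_epoch"], val_loss=manifest["val_loss"],
        )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ResidueClassifier:
    """Per-residue binary classifier for one named feature.

    Parameters
    ----------
    train_data, val_data
        Sequences of ``(ProteinRecord, LabelTrack)`` pairs for the training
        and validation splits.  Masked-out residues never enter the loss.
    feature
        The controlled feature name this classifier predicts.
    backbone
        A backbone instance (see :mod:`featshift.backbones`).  In
        ``fine_tune`` mode, LoRA adapters are attached to its attention
        projections when it exposes adaptable sites.
    """

    def __init__(self, train_data, val_data, feature: str, backbone,
                 head_config: HeadConfig = HeadConfig(),
                 lora_config: LoRAConfig = LoRAConfig(),
                 training_config: TrainingConfig = TrainingConfig()):
        self.train_data = list(train_data)
        self.val_data = list(val_data)
        self.feature = feature
        self.backbone = backbone
        self.head_config = head_config
        self.lora_config = lora_config
        self.training_config = training_config
        self._validate()

    @classmethod
    def from_dataset(cls, proteins: Sequence[ProteinRecord],
                     tracks: Sequence[LabelTrack], split: dict[str, str],
                     feature: str, backbone, **kwargs) -> "ResidueClassifier":
        """Build a model from a full dataset plus a split assignment."""
        by_id = {t.protein_id: t for t in tracks if t.feature == feature}
        data = {name: [] for name in ("train", "validation", "test")}
        for p in proteins:
            track = by_id.get(p.id)
            if track is None or not track.mask.any():
                continue
            data[split[p.id]].append((p, track))
        return cls(data["train"], data["validation"], feature, backbone, **kwargs)

    def _validate(self) -> None:
        if not self.train_data:
            raise ValueError("empty training set")
        for protein, track in self.train_data + self.val_data:
            if track.length != protein.length:
                raise ValueError(
                    f"{protein.id}: track length {track.length} != protein "
                    f"length {protein.length}"
                )
            if track.feature != self.feature:
                raise ValueError(f"track for {track.feature!r}, expected "
                                 f"{self.feature!r}")
        if not any(t.mask.any() for _, t in self.train_data):
            raise ValueError("all training residues are masked out")
        observed = np.concatenate(
            [t.labels[t.mask == 1] for _, t in self.train_data]
        )
        if observed.min() == observed.max():
            warnings.warn(
                "training labels are single-class; AUROC will be undefined "
                "downstream"
            )

    def _chunks(self, protein: ProteinRecord, track: LabelTrack):
        """Split long proteins into max_length training chunks."""
        L = protein.length
        m = self.training_config.max_length
        for start in range(0, L, m):
            end = min(start + m, L)
            yield (protein.sequence[start:end], track.labels[start:end],
                   track.mask[start:end])

    def fit(self) -> "ResidueClassifierResults":
        """Train for the configured epochs and keep the best checkpoint."""
        cfg = self.training_config
        rng = np.random.default_rng(cfg.seed)

        backbone = self.backbone
        fine_tune = cfg.mode == "fine_tune"
        if fine_tune and backbone.adaptable_sites:
            backbone = attach_lora(backbone, self.lora_config, seed=cfg.seed)
        head = ClassificationHead(backbone.embedding_dim, self.head_config, rng)

        class_weights = None
        if cfg.class_weighting:
            obs = np.concatenate(
                [t.labels[t.mask == 1] for _, t in self.train_data]
            )
            freq = np.array([(obs == 0).mean(), (obs == 1).mean()])
            freq = np.clip(freq, 1e-12, None)
            class_weights = (1.0 / freq) / (1.0 / freq).sum() * 2.0

        train_chunks = [c for p, t in self.train_data for c in self._chunks(p, t)]
        val_chunks = [c for p, t in self.val_data for c in self._chunks(p, t)]
        train_chunks = [c for c in train_chunks if c[2].any()]
        val_chunks = [c for c in val_chunks if c[2].any()]

        emb_cache: dict[str, np.ndarray] | None = None
        if not fine_tune or not backbone.adaptable_sites:
            emb_cache = {seq: backbone.embed(seq)
                         for seq, _, _ in train_chunks + val_chunks}

        def forward_logits(seq: str, training: bool) -> Tensor:
            if emb_cache is not None:
                x = Tensor(emb_cache[seq])
            else:
                x = backbone.forward(seq, training=training, rng=rng)
            return head.logits(x, training=training, rng=rng)

        params = head.parameters()
        if fine_tune:
            params = params + backbone.trainable_parameters()
        optimizer = Adam(params, lr=cfg.learning_rate)

        def pooled_loss(chunks) -> float:
            total, count = 0.0, 0
            for seq, labels, mask in chunks:
                n = int(mask.sum())
                loss = masked_cross_entropy(
                    forward_logits(seq, training=False), labels, mask,
                    class_weights=class_weights)
                total += float(loss.data) * n
                count += n
            return total / count if count else float("nan")

        history: list[dict] = []
        best_state: dict[str, np.ndarray] | None = None
        best_epoch, best_val = -1, np.inf
        named = _named_trainable(head, backbone)

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_chunks))
            epoch_total, epoch_count = 0.0, 0
            for batch_start in range(0, len(order), cfg.batch_size):
                batch = order[batch_start: batch_start + cfg.batch_size]
                optimizer.zero_grad()
                for idx in batch:
                    seq, labels, mask = train_chunks[idx]
                    loss = masked_cross_entropy(
                        forward_logits(seq, training=True), labels, mask,
                        class_weights=class_weights)
                    (loss * (1.0 / len(batch))).backward()
                    epoch_total += float(loss.data) * int(mask.sum())
                    epoch_count += int(mask.sum())
                optimizer.step()
            val_loss = pooled_loss(val_chunks) if val_chunks else epoch_total / epoch_count
            history.append({
                "epoch": epoch + 1,
                "train_loss": epoch_total / epoch_count,
                "val_loss": val_loss,
            })
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch + 1
                best_state = {k: v.data.copy() for k, v in named.items()}

        for k, tensor in named.items():
            tensor.data = best_state[k]

        checkpoint = Checkpoint(
            feature=self.feature, backbone=backbone, head=head,
            head_config=self.head_config,
            lora_config=self.lora_config if (fine_tune and backbone.adaptable_sites)
            else None,
            training_config=cfg, best_epoch=best_epoch, val_loss=best_val,
        )
        return ResidueClassifierResults(self, checkpoint, history)


class ResidueClassifierResults:
    """Fit results: the selected checkpoint, loss history and evaluators."""

    def __init__(self, model: ResidueClassifier, checkpoint: Checkpoint,
                 history: list[dict]):
        self.model = model
        self.checkpoint = checkpoint
        self.history = history
        self.best_epoch = checkpoint.best_epoch
        self.val_loss = checkpoint.val_loss

    @property
    def n_trainable_parameters(self) -> int:
        named = _named_trainable(self.checkpoint.head, self.checkpoint.backbone)
        return sum(v.data.size for v in named.values())

    def predict(self, proteins: Sequence[ProteinRecord]) -> list[PredictionProfile]:
        return self.checkpoint.predict(proteins)

    def evaluate(self, proteins: Sequence[ProteinRecord],
                 tracks: Sequence[LabelTrack]):
        from .metrics import compute_metrics
        profiles = self.predict(proteins)
        return compute_metrics(tracks, profiles,
                               model=self.checkpoint.backbone.name)

    def summary(self) -> str:
        cfg = self.model.training_config
        lines = [
            "Per-residue feature classifier",
            "=" * 46,
            f"feature:              {self.model.feature}",
            f"backbone:             {self.checkpoint.backbone.name}",
            f"mode:                 {cfg.mode}",
            f"trainable parameters: {self.n_trainable_parameters}",
            f"epochs:               {cfg.epochs} (best: {self.best_epoch})",
            f"validation loss:      {self.val_loss:.6f}",
            "-" * 46,
            f"{'epoch':>5} {'train_loss':>12} {'val_loss':>12}",
        ]
        for row in self.history:
            lines.append(f"{row['epoch']:>5} {row['train_loss']:>12.6f} "
                         f"{row['val_loss']:>12.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _predict_probs(checkpoint: Checkpoint, sequence: str) -> np.ndarray:
    x = Tensor(checkpoint.backbone.embed(sequence))
    logits = checkpoint.head.logits(x, training=False)
    return softmax(logits).data[:, 1]


def predict(checkpoint: Checkpoint, proteins: Sequence[ProteinRecord],
            overlap: int = 64) -> list[PredictionProfile]:
    """Run inference, chunking sequences longer than the configured maximum.

    Long sequences are processed in max-length windows that overlap by
    ``overlap`` residues; probabilities in overlapping regions are averaged.
    Deterministic: dropout is inactive at inference.
    """
    max_len = checkpoint.training_config.max_length
    profiles: list[PredictionProfile] = []
    for protein in proteins:
        L = protein.length
        if L <= max_len:
            probs = _predict_probs(checkpoint, protein.sequence)
        else:
            step = max_len - min(overlap, max_len // 2)
            acc = np.zeros(L)
            weight = np.zeros(L)
            start = 0
            while start < L:
                end = min(start + max_len, L)
                chunk = protein.sequence[start:end]
                acc[start:end] += _predict_probs(checkpoint, chunk)
                weight[start:end] += 1.0
                if end == L:
                    break
                start += step
            probs = acc / weight
        profiles.append(PredictionProfile(protein.id, checkpoint.feature, probs))
    return profiles


def write_prediction_tsv(profiles: Sequence[PredictionProfile],
                         path: str | Path) -> None:
    """Long-format TSV: protein_id, feature, position (1-based), probability, label."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfeature\tposition\tprobability\tlabel\n")
        for prof in profiles:
            labels = prof.labels_pred
            for i, p in enumerate(prof.probabilities):
                fh.write(f"{prof.protein_id}\t{prof.feature}\t{i + 1}\t"
                         f"{p:.6f}\t{labels[i]}\n")
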