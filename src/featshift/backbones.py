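"""Sequence encoder backbones and the low-rank adaptation (LoRA) contract.

A backbone maps an L-residue protein sequence to an L × embedding_dim real
matrix.  Two desk-scale backbones are provided:

``onehot_window``
    A deterministic, parameter-free encoder: each residue is represented by
    the one-hot identities of the residues in a ±w window around it.  Any
    feature that is a function of local sequence context is exactly learnable
    from these embeddings, which makes it the reference backbone for
    separable fixture tasks.

``tiny_transformer``
    A small randomly-initialised transformer encoder with genuine
    query/key/value/output projections in each attention block, so the LoRA
    fine-tuning path is exercised end to end.  Its base weights play the role
    of frozen pretrained weights.

LoRA replaces each targeted projection ``W`` by ``W + (alpha/rank)·(B·A)``
with ``A`` (rank × d_in) drawn small and ``B`` (d_out × rank) zero-initialised,
so the adapted model is bit-identical to the frozen one until training moves
``B`` away from zero.  Trainable backbone parameters number exactly
``rank·(d_in + d_out)`` per adapted site.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np

from .annotations import AMINO_ACIDS
from .nn import LayerNorm, Linear, Tensor, relu, softmax

__all__ = [
    "LoRAConfig",
    "LoRALinear",
    "OneHotWindowBackbone",
    "TinyTransformerBackbone",
    "toy_backbone",
    "attach_lora",
]

LORA_SITES = ("query", "key", "value", "output")

_TOKENS = AMINO_ACIDS + "X"
_TOKEN_INDEX = {aa: i for i, aa in enumerate(_TOKENS)}


@dataclasses.dataclass(frozen=True)
class LoRAConfig:
    rank: int = 4
    alpha: float = 1.0
    target_sites: tuple[str, ...] = LORA_SITES

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        unknown = set(self.target_sites) - set(LORA_SITES)
        if unknown:
            raise ValueError(f"unknown LoRA target sites {sorted(unknown)}")


class LoRALinear:
    """A frozen affine map plus a trainable rank-decomposed update."""

    def __init__(self, base: Linear, rank: int, alpha: float,
                 rng: np.random.Generator):
        self.W = Tensor(base.W.data.copy())          # frozen
        self.b = Tensor(base.b.data.copy())          # frozen
        self.A = Tensor(rng.normal(0.0, 0.01, size=(rank, base.d_in)),
                        requires_grad=True)
        self.B = Tensor(np.zeros((base.d_out, rank)), requires_grad=True)
        self.scale = alpha / rank
        self.d_in, self.d_out = base.d_in, base.d_out

    def __call__(self, x: Tensor) -> Tensor:
        delta = self.B.matmul(self.A).transpose() * self.scale  # (d_in, d_out)
        return x.matmul(self.W + delta) + self.b

    def parameters(self) -> list[Tensor]:
        return [self.A, self.B]

    def n_trainable(self) -> int:
        return self.A.data.size + self.B.data.size


def _token_onehot(sequence: str) -> np.ndarray:
    """(L, 20) one-hot rows; the unknown residue X maps to an all-zero row."""
    out = np.zeros((len(sequence), len(AMINO_ACIDS)))
    for i, aa in enumerate(sequence):
        if aa != "X":
            out[i, _TOKEN_INDEX[aa]] = 1.0
    return out


class OneHotWindowBackbone:
    """Deterministic windowed one-hot encoder (no trainable parameters)."""

    def __init__(self, window: int = 1):
        if window < 0:
            raise ValueError("window half-width must be >= 0")
        self.window = window
        self.name = f"onehot_window(w={window})"
        self.spec = {"kind": "onehot_window", "params": {"window": window}}
        self.embedding_dim = (2 * window + 1) * len(AMINO_ACIDS)
        self.adaptable_sites: dict[str, list] = {}

    def embed(self, sequence: str) -> np.ndarray:
        base = _token_onehot(sequence)
        L, d = base.shape
        cols = []
        for off in range(-self.window, self.window + 1):
            shifted = np.zeros_like(base)
            if off < 0:
                shifted[-off:] = base[:L + off]
            elif off > 0:
                shifted[:L - off] = base[off:]
            else:
                shifted = base
            cols.append(shifted)
        return np.concatenate(cols, axis=1)

    def forward(self, sequence: str, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        return Tensor(self.embed(sequence))

    def trainable_parameters(self) -> list[Tensor]:
        return []


class _AttentionBlock:
    def __init__(self, dim: int, rng: np.random.Generator):
        self.sites = {
            "query": Linear(dim, dim, rng),
            "key": Linear(dim, dim, rng),
            "value": Linear(dim, dim, rng),
            "output": Linear(dim, dim, rng),
        }
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, 2 * dim, rng)
        self.ff2 = Linear(2 * dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.dim = dim

    def __call__(self, h: Tensor) -> Tensor:
        q = self.sites["query"](h)
        k = self.sites["key"](h)
        v = self.sites["value"](h)
        scores = q.matmul(k.transpose()) * (1.0 / np.sqrt(self.dim))
        attn = softmax(scores)
        ctx = self.sites["output"](attn.matmul(v))
        h = self.norm1(h + ctx)
        ff = self.ff2(relu(self.ff1(h)))
        return self.norm2(h + ff)


class TinyTransformerBackbone:
    """Small single-head transformer encoder with frozen random base weights."""

    def __init__(self, n_layers: int = 1, dim: int = 32, seed: int = 0):
        if n_layers < 1 or dim < 1:
            raise ValueError("n_layers and dim must be positive")
        rng = np.random.default_rng(seed)
        self.name = f"tiny_transformer(L={n_layers},d={dim},seed={seed})"
        self.spec = {"kind": "tiny_transformer",
                     "params": {"n_layers": n_layers, "dim": dim, "seed": seed}}
        self.embedding_dim = dim
        self.dim = dim
        self.token_embedding = rng.normal(0.0, 1.0, size=(len(_TOKENS), dim))
        self.blocks = [_AttentionBlock(dim, rng) for _ in range(n_layers)]
        self.adaptable_sites = {
            site: [block.sites[site] for block in self.blocks]
            for site in LORA_SITES
        }

    def _input(self, sequence: str) -> np.ndarray:
        idx = np.array([_TOKEN_INDEX[aa] for aa in sequence])
        h = self.token_embedding[idx]
        # fixed sinusoidal positional encoding
        L, d = h.shape
        pos = np.arange(L)[:, None]
        div = np.exp(-np.log(10000.0) * np.arange(0, d, 2) / d)
        pe = np.zeros((L, d))
        pe[:, 0::2] = np.sin(pos * div)
        pe[:, 1::2] = np.cos(pos * div[: pe[:, 1::2].shape[1]])
        return h + pe

    def forward(self, sequence: str, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = Tensor(self._input(sequence))
        for block in self.blocks:
            h = block(h)
        return h

    def embed(self, sequence: str) -> np.ndarray:
        return self.forward(sequence).data

    def trainable_parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for block in self.blocks:
            for site in LORA_SITES:
                layer = block.sites[site]
                if isinstance(layer, LoRALinear):
                    params.extend(layer.parameters())
        return params

    def n_trainable(self) -> int:
        return sum(p.data.size for p in self.trainable_parameters())


def toy_backbone(kind: str, **params):
    """Construct a desk-scale backbone by name.

    ``kind`` is ``"onehot_window"`` (params: ``window``) or
    ``"tiny_transformer"`` (params: ``n_layers``, ``dim``, ``seed``).
    """
    if kind == "onehot_window":
        return OneHotWindowBackbone(**params)
    if kind == "tiny_transformer":
        return TinyTransformerBackbone(**params)
    raise ValueError(f"unknown backbone kind {kind!r}")


def attach_lora(backbone, config: LoRAConfig, seed: int = 0):
    """Return a copy of ``backbone`` with LoRA adapters at the target sites.

    The original backbone is left untouched.  With B zero-initialised the
    adapted copy's forward pass is bit-identical to the frozen one.
    """
    missing = [s for s in config.target_sites if s not in backbone.adaptable_sites]
    if missing:
        raise ValueError(
            f"backbone {backbone.name!r} lacks adaptable sites {missing}"
        )
    adapted = copy.deepcopy(backbone)
    rng = np.random.default_rng(seed)
    for block in adapted.blocks:
        for site in config.target_sites:
            block.sites[site] = LoRALinear(block.sites[site], config.rank,
                                           config.alpha, rng)
    adapted.name = f"{backbone.name}+lora(r={config.rank},a={config.alpha})"
    return adapted
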