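"""The graph-embedded deep neural network and its ablations.

One parameterized feedforward architecture covers four modes:

========  =======================  =========================
mode      SNP -> gene layer        gene -> gene layer
========  =======================  =========================
dnn       (no gene layers: plain dense chain)
e_dnn     masked by A (eQTL)       dense
gedfn     dense                    masked by A' (PPI)
gednn     masked by A              masked by A'
========  =======================  =========================

Gene-layer modes use the layer chain p -> q -> q -> hidden_widths -> 2; the
plain DNN uses p -> hidden_widths -> 2. Masking is a Hadamard product of the
weight matrix with the binary adjacency, enforced at initialization, in every
forward pass, and after every optimizer step, so masked weights are exactly
zero throughout training.

Training uses ReLU activations, inverted dropout on hidden activations
(``dropout_keep`` is the KEEP probability), a two-unit softmax head, binary
cross-entropy on the positive-class probability plus an alpha-weighted
L2 (default) or L1 penalty on all weight matrices, and the Adam optimizer.
Everything is implemented on numpy arrays and is bit-reproducible from the
seed on a fixed machine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .graph import GeneGraphMask, SnpGeneMask

__all__ = [
    "ModelConfig",
    "ModelState",
    "init_model",
    "forward",
    "loss",
    "train_step",
    "save_checkpoint",
    "load_checkpoint",
    "MODES",
]

MODES = ("dnn", "e_dnn", "gedfn", "gednn")

# Adam moment decay rates and denominator guard (standard values)
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the tuned settings: learning rate
    0.001, batch size 8, dropout keep 0.9, hidden widths [128, 16] when a gene
    layer exists and [256, 64, 16] otherwise."""

    mode: Literal["dnn", "e_dnn", "gedfn", "gednn"] = "gednn"
    hidden_widths: tuple[int, ...] | None = None  # None -> mode default
    dropout_keep: float = 0.9
    alpha: float = 1e-4
    reg_norm: Literal["l2", "l1"] = "l2"
    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    clamp_eps: float = 1e-7
    standardize: bool = True
    bias_init: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.reg_norm not in ("l2", "l1"):
            raise ValueError(f"unknown reg_norm {self.reg_norm!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.hidden_widths is not None:
            self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
            if any(w < 1 for w in self.hidden_widths):
                raise ValueError("hidden widths must be positive")

    @property
    def has_gene_layer(self) -> bool:
        return self.mode != "dnn"

    def resolved_hidden_widths(self) -> tuple[int, ...]:
        if self.hidden_widths is not None:
            return self.hidden_widths
        return (128, 16) if self.has_gene_layer else (256, 64, 16)


@dataclass
class ModelState:
    """Weights, biases, per-layer masks (None for dense layers), Adam moments,
    and the RNG that drives dropout."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    layer_masks: list[np.ndarray | None]
    config: ModelConfig
    dims: list[int]
    rng: np.random.Generator
    snp_ids: list[str] | None = None
    gene_ids: list[str] | None = None
    adam_m: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    adam_v: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    adam_t: int = 0
    last_loss: float = float("nan")

    @property
    def n_layers(self) -> int:
        return len(self.weights)


def _check_masks(
    config: ModelConfig,
    masks: tuple[SnpGeneMask | None, GeneGraphMask | None] | None,
    p: int,
) -> tuple[SnpGeneMask | None, GeneGraphMask | None]:
    a, a_prime = (None, None) if masks is None else masks
    need_a = config.mode in ("e_dnn", "gednn")
    need_ap = config.mode in ("gedfn", "gednn")
    if need_a and a is None:
        raise ValueError(f"mode {config.mode!r} requires a SNP-gene mask")
    if need_ap and a_prime is None:
        raise ValueError(f"mode {config.mode!r} requires a gene-gene mask")
    if not need_a and a is not None and config.mode == "dnn":
        raise ValueError("mode 'dnn' takes no masks")
    if not need_ap and a_prime is not None and config.mode == "dnn":
        raise ValueError("mode 'dnn' takes no masks")
    if a is not None and a.matrix.shape[0] != p:
        raise ValueError(f"SNP-gene mask has {a.matrix.shape[0]} rows, input has p={p}")
    if a is not None and a_prime is not None:
        if a.matrix.shape[1] != a_prime.matrix.shape[0]:
            raise ValueError("SNP-gene and gene-gene masks disagree on gene count")
    return (a if need_a else None), (a_prime if need_ap else None)


def init_model(
    config: ModelConfig,
    masks: tuple[SnpGeneMask | None, GeneGraphMask | None] | None,
    p: int,
    q: int | None = None,
    seed: int | None = None,
) -> ModelState:
    """Build an initialized model.

    Weights use He-uniform initialization, U(-1, 1) scaled per output unit by
    sqrt(6 / fan_in), where a masked layer's fan-in is the unit's mask degree
    (the number of inputs actually wired to it); masked weight entries are
    zeroed at birth. Two ReLU dead-unit guards apply uniformly to masked and
    dense layers alike (so masking stays the only difference between modes):
    hidden biases start at the small positive ``bias_init`` rather than zero,
    and square hidden layers get a nonnegative diagonal (an identity-leaning
    start), which keeps gene self-connections through the graph-masked
    gene-gene layer from being irrecoverably dead at birth. The output-layer
    bias is zero. Deterministic given the seed.
    """
    if p < 1:
        raise ValueError("p must be positive")
    a, a_prime = _check_masks(config, masks, p)
    if config.has_gene_layer:
        if a is not None:
            q = a.matrix.shape[1]
        elif a_prime is not None:
            q = a_prime.matrix.shape[0]
        if q is None or q < 1:
            raise ValueError("gene-layer modes need q (or masks that define it)")
        dims = [p, q, q, *config.resolved_hidden_widths(), 2]
        layer_masks: list[np.ndarray | None] = [
            a.matrix if a is not None else None,
            a_prime.matrix if a_prime is not None else None,
        ] + [None] * (len(dims) - 3)
    else:
        dims = [p, *config.resolved_hidden_widths(), 2]
        layer_masks = [None] * (len(dims) - 1)

    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights, biases = [], []
    for l, (n_in, n_out) in enumerate(zip(dims[:-1], dims[1:])):
        w = rng.uniform(-1.0, 1.0, size=(n_in, n_out))
        mask = layer_masks[l]
        fan_in = mask.sum(axis=0) if mask is not None else np.full(n_out, float(n_in))
        w *= np.sqrt(6.0 / np.maximum(fan_in, 1.0))
        if n_in == n_out and l < len(dims) - 2:  # identity-leaning square layers
            diag = np.arange(n_in)
            w[diag, diag] = np.abs(w[diag, diag])
        if mask is not None:
            w *= mask
        weights.append(w)
        hidden = l < len(dims) - 2
        biases.append(np.full(n_out, config.bias_init if hidden else 0.0))

    return ModelState(
        weights=weights,
        biases=biases,
        layer_masks=layer_masks,
        config=config,
        dims=dims,
        rng=rng,
        snp_ids=list(a.snp_ids) if a is not None else None,
        gene_ids=(
            list(a.gene_ids) if a is not None
            else list(a_prime.gene_ids) if a_prime is not None else None
        ),
        adam_m=[(np.zeros_like(w), np.zeros(w.shape[1])) for w in weights],
        adam_v=[(np.zeros_like(w), np.zeros(w.shape[1])) for w in weights],
    )


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _effective_weight(state: ModelState, l: int) -> np.ndarray:
    # masked entries are maintained exactly zero (at init and after every
    # optimizer step), so W already equals the Hadamard product W ⊙ mask
    return state.weights[l]


def _forward_cached(state: ModelState, x: np.ndarray, train_mode: bool):
    """Forward pass keeping per-layer inputs, pre-activations and dropout
    multipliers for backprop."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != state.dims[0]:
        raise ValueError(f"input has {x.shape[-1]} features, model expects {state.dims[0]}")
    keep = state.config.dropout_keep
    h = x
    inputs, preacts, dropmasks = [], [], []
    last = state.n_layers - 1
    for l in range(state.n_layers):
        inputs.append(h)
        z = h @ _effective_weight(state, l) + state.biases[l]
        preacts.append(z)
        if l < last:
            h = _relu(z)
            if train_mode and keep < 1.0:
                d = (state.rng.random(h.shape) < keep) / keep
                h = h * d
                dropmasks.append(d)
            else:
                dropmasks.append(None)
        else:
            h = _softmax(z)
            dropmasks.append(None)
    return h, inputs, preacts, dropmasks


def forward(state: ModelState, x: np.ndarray, train_mode: bool = False) -> np.ndarray:
    """Class-probability matrix (batch x 2); rows sum to 1. Dropout is applied
    only when ``train_mode`` (and consumes the state RNG)."""
    probs, *_ = _forward_cached(state, x, train_mode)
    return probs


def _penalty(state: ModelState) -> float:
    cfg = state.config
    if cfg.alpha == 0:
        return 0.0
    total = 0.0
    for l in range(state.n_layers):
        w = _effective_weight(state, l)
        total += float((w ** 2).sum()) if cfg.reg_norm == "l2" else float(np.abs(w).sum())
    return cfg.alpha * total


def loss(probs: np.ndarray, y: np.ndarray, state: ModelState) -> float:
    """Mean binary cross-entropy on the positive-class probability, plus the
    alpha-weighted weight penalty; probabilities clamped away from {0,1}."""
    y = np.asarray(y, dtype=np.float64)
    eps = state.config.clamp_eps
    p1 = np.clip(probs[:, 1], eps, 1.0 - eps)
    ce = -float(np.mean(y * np.log(p1) + (1.0 - y) * np.log(1.0 - p1)))
    return ce + _penalty(state)


def train_step(state: ModelState, batch: np.ndarray, labels: np.ndarray) -> ModelState:
    """One Adam update on all parameters.

    Masked gradients are zeroed before the update and masks re-applied to the
    weights afterwards, so masked entries stay exactly zero. The batch loss is
    recorded on ``state.last_loss``. Raises if the loss goes non-finite.
    """
    y = np.asarray(labels, dtype=np.float64)
    probs, inputs, preacts, dropmasks = _forward_cached(state, batch, train_mode=True)
    state.last_loss = loss(probs, y, state)
    if not np.isfinite(state.last_loss):
        raise FloatingPointError("training diverged: non-finite loss")

    n = batch.shape[0]
    cfg = state.config
    onehot = np.column_stack([1.0 - y, y])
    delta = (probs - onehot) / n  # softmax + cross-entropy gradient
    grads_w: list[np.ndarray] = [None] * state.n_layers  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * state.n_layers  # type: ignore[list-item]
    for l in range(state.n_layers - 1, -1, -1):
        w_eff = _effective_weight(state, l)
        gw = inputs[l].T @ delta
        if cfg.alpha > 0:
            gw += cfg.alpha * (2.0 * w_eff if cfg.reg_norm == "l2" else np.sign(w_eff))
        mask = state.layer_masks[l]
        if mask is not None:
            gw *= mask
        grads_w[l] = gw
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ w_eff.T) * (preacts[l - 1] > 0)
            if dropmasks[l - 1] is not None:
                delta = delta * dropmasks[l - 1]

    state.adam_t += 1
    t = state.adam_t
    lr = cfg.learning_rate
    for l in range(state.n_layers):
        for param, grad, m, v in (
            (state.weights[l], grads_w[l], 0, 0),
            (state.biases[l], grads_b[l], 1, 1),
        ):
            mom = state.adam_m[l][m]
            vel = state.adam_v[l][v]
            mom *= _ADAM_B1
            mom += (1 - _ADAM_B1) * grad
            vel *= _ADAM_B2
            vel += (1 - _ADAM_B2) * grad ** 2
            m_hat = mom / (1 - _ADAM_B1 ** t)
            v_hat = vel / (1 - _ADAM_B2 ** t)
            param -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        mask = state.layer_masks[l]
        if mask is not None:
            state.weights[l] *= mask
    return state


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Serialize weights, biases, masks, ids and config into one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for l in range(state.n_layers):
        arrays[f"W{l}"] = state.weights[l]
        arrays[f"b{l}"] = state.biases[l]
        if state.layer_masks[l] is not None:
            arrays[f"mask{l}"] = state.layer_masks[l]
    arrays["dims"] = np.array(state.dims)
    meta = {
        "config": dataclasses.asdict(state.config),
        "snp_ids": state.snp_ids,
        "gene_ids": state.gene_ids,
        "n_layers": state.n_layers,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        cfg_dict = meta["config"]
        if cfg_dict.get("hidden_widths") is not None:
            cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        config = ModelConfig(**cfg_dict)
        n_layers = meta["n_layers"]
        weights = [npz[f"W{l}"] for l in range(n_layers)]
        biases = [npz[f"b{l}"] for l in range(n_layers)]
        layer_masks = [npz[f"mask{l}"] if f"mask{l}" in npz else None for l in range(n_layers)]
        dims = npz["dims"].tolist()
    return ModelState(
        weights=weights,
        biases=biases,
        layer_masks=layer_masks,
        config=config,
        dims=dims,
        rng=np.random.default_rng(config.seed),
        snp_ids=meta["snp_ids"],
        gene_ids=meta["gene_ids"],
        adam_m=[(np.zeros_like(w), np.zeros(w.shape[1])) for w in weights],
        adam_v=[(np.zeros_like(w), np.zeros(w.shape[1])) for w in weights],
    )
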