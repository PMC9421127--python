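"""Splitting, training loops, ROC/AUC evaluation and the sample-size sweep.

The evaluation protocol is shared across all four model modes: one stratified
train/validation/test split (default 0.8/0.1/0.1), early stopping on the
validation AUC with best-weight restore, and a held-out test AUC computed as
the trapezoidal area under the ROC curve (equal to the Mann-Whitney statistic
with ties counted one half). Modes are compared on identical splits, seeds
and preprocessing so that the adjacency masking is the only difference.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .graph import GeneGraphMask, SnpGeneMask
from .io_formats import GenotypeMatrix, LabelVector
from .model import ModelConfig, ModelState, forward, init_model, train_step

__all__ = [
    "SplitSpec",
    "EvalResult",
    "stratified_split",
    "roc_auc",
    "fit",
    "train_and_evaluate",
    "run_comparison",
    "sample_size_sweep",
    "stratified_subsample",
]

log = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    test_fraction: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs):
            raise ValueError("all split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class EvalResult:
    mode: str
    auc: float
    roc_points: np.ndarray  # (k, 2) columns (fpr, tpr), both nondecreasing
    n_train: int
    n_test: int
    seed: int
    history: dict = field(default_factory=dict)


def _allocate(n: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to fractions."""
    raw = [n * f for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # biggest shortfall first
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def stratified_split(
    labels: LabelVector | np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index sets with per-class
    proportions within one sample of the global proportions; deterministic
    under ``spec.seed``."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("stratified split needs both classes present")
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)
    parts: list[list[np.ndarray]] = [[], [], []]
    strata = [np.flatnonzero(y == c) for c in classes] if spec.stratified else [np.arange(len(y))]
    for idx in strata:
        idx = rng.permutation(idx)
        counts = _allocate(len(idx), fracs)
        if spec.stratified and any(c == 0 for c in counts):
            raise ValueError("a split would receive zero samples of a class")
        bounds = np.cumsum(counts)
        parts[0].append(idx[: bounds[0]])
        parts[1].append(idx[bounds[0]: bounds[1]])
        parts[2].append(idx[bounds[1]:])
    out = tuple(np.sort(np.concatenate(p)) for p in parts)
    if not spec.stratified and any(len(np.unique(y[p])) < 2 for p in out):
        raise ValueError("a split received zero samples of a class")
    return out


def roc_auc(scores: np.ndarray, labels: LabelVector | np.ndarray) -> tuple[float, np.ndarray]:
    """AUC and ROC points from positive-class scores.

    The AUC is the trapezoidal area under the threshold-swept ROC curve,
    which equals the Mann-Whitney probability that a random case outscores a
    random control with ties counted one half.
    """
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def _standardizer(x_train: np.ndarray):
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return lambda x: (x - mu) / sd


def fit(
    state: ModelState,
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
) -> tuple[ModelState, dict]:
    """Mini-batch Adam training with early stopping on validation AUC.

    Epoch shuffling comes from the state RNG (shared with dropout), so a run
    is fully determined by the model seed. The best-validation-AUC weights are
    restored at the end. Returns the trained state and a history dict with
    per-epoch train loss and validation AUC.
    """
    cfg = state.config
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if cfg.standardize:
        scale = _standardizer(x[train_idx])
        x = scale(x)
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]
    history: dict = {"train_loss": [], "val_auc": []}
    best_auc, best_weights, best_epoch = -np.inf, None, -1
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = state.rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start: start + cfg.batch_size]
            train_step(state, xt[sel], yt[sel])
            losses.append(state.last_loss)
        val_auc, _ = roc_auc(forward(state, xv)[:, 1], yv)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, since_best = val_auc, epoch, 0
            best_weights = (
                [w.copy() for w in state.weights],
                [b.copy() for b in state.biases],
            )
        else:
            since_best += 1
            if cfg.patience and since_best >= cfg.patience:
                break
    if best_weights is not None:
        state.weights = best_weights[0]
        state.biases = best_weights[1]
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = best_auc
    return state, history


def train_and_evaluate(
    x: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    masks: tuple[SnpGeneMask | None, GeneGraphMask | None] | None,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    seed: int | None = None,
) -> tuple[ModelState, EvalResult]:
    """Initialize, fit and score one model on a fixed split."""
    train_idx, val_idx, test_idx = split
    state = init_model(config, masks, p=x.shape[1], seed=seed)
    state, history = fit(state, x, y, train_idx, val_idx)
    xs = np.asarray(x, dtype=np.float64)
    if config.standardize:
        xs = _standardizer(xs[train_idx])(xs)
    scores = forward(state, xs[test_idx])[:, 1]
    auc, points = roc_auc(scores, np.asarray(y)[test_idx])
    result = EvalResult(
        mode=config.mode,
        auc=auc,
        roc_points=points,
        n_train=len(train_idx),
        n_test=len(test_idx),
        seed=seed if seed is not None else config.seed,
        history=history,
    )
    log.info("mode=%s test AUC=%.4f (best epoch %d)", config.mode, auc, history["best_epoch"])
    return state, result


def _mode_masks(mode: str, a: SnpGeneMask, a_prime: GeneGraphMask):
    if mode == "dnn":
        return None
    return (a if mode in ("e_dnn", "gednn") else None,
            a_prime if mode in ("gedfn", "gednn") else None)


def run_comparison(
    geno: GenotypeMatrix,
    labels: LabelVector,
    snp_gene: SnpGeneMask,
    gene_graph: GeneGraphMask,
    spec: SplitSpec | None = None,
    configs: dict[str, ModelConfig] | None = None,
    modes: Sequence[str] = ("dnn", "e_dnn", "gedfn", "gednn"),
    seed: int = 0,
) -> list[EvalResult]:
    """Train every mode on the identical split/seed and return per-mode results.

    Inputs are restricted to the SNPs retained in the SNP-gene mask for every
    mode alike, so the modes differ only in layer masking (plus the default
    width convention: [128, 16] with a gene layer, [256, 64, 16] without).
    """
    spec = spec or SplitSpec(seed=seed)
    geno = geno.subset_snps(snp_gene.snp_ids)
    if geno.sample_ids != labels.sample_ids:
        labels = labels.subset(geno.sample_ids)
    x = geno.calls.astype(np.float64)
    y = labels.labels.astype(np.int8)
    split = stratified_split(labels, spec)
    results = []
    for mode in modes:
        cfg = (configs or {}).get(mode) or ModelConfig(mode=mode, seed=seed)
        if cfg.mode != mode:
            raise ValueError(f"config for {mode!r} has mode {cfg.mode!r}")
        _, res = train_and_evaluate(x, y, cfg, _mode_masks(mode, snp_gene, gene_graph),
                                    split, seed=seed)
        results.append(res)
    return results


def stratified_subsample(
    labels: LabelVector | np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-proportion-preserving subsample of ``size`` indices (within one
    sample of the global proportion per class)."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if size > len(y):
        raise ValueError(f"requested size {size} exceeds n={len(y)}")
    classes, counts = np.unique(y, return_counts=True)
    take = _allocate(size, counts / len(y))
    chosen = [
        rng.choice(np.flatnonzero(y == c), size=k, replace=False)
        for c, k in zip(classes, take)
    ]
    return np.sort(np.concatenate(chosen))


def sample_size_sweep(
    geno: GenotypeMatrix,
    labels: LabelVector,
    snp_gene: SnpGeneMask,
    gene_graph: GeneGraphMask,
    sizes: Sequence[int] = (500, 400, 300, 200, 100),
    seeds: Sequence[int] = (0,),
    mode: str = "gednn",
    config: ModelConfig | None = None,
    spec: SplitSpec | None = None,
) -> pd.DataFrame:
    """Train/evaluate at shrinking class-balanced subsample sizes.

    Returns a tidy table (size, seed, auc). Each cell draws its own
    subsample, splits it stratified, and trains one model.
    """
    geno = geno.subset_snps(snp_gene.snp_ids)
    if geno.sample_ids != labels.sample_ids:
        labels = labels.subset(geno.sample_ids)
    y_all = labels.labels.astype(np.int8)
    x_all = geno.calls.astype(np.float64)
    if max(sizes) > len(y_all):
        raise ValueError(f"max size {max(sizes)} exceeds n={len(y_all)}")
    base_cfg = config or ModelConfig(mode=mode)
    if min(sizes) < 2 * base_cfg.batch_size:
        raise ValueError("smallest size must be at least twice the batch size")
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        for size in sizes:
            sub = stratified_subsample(y_all, size, rng)
            cfg = dataclasses.replace(base_cfg, seed=seed)
            split_spec = spec or SplitSpec(seed=seed)
            split = stratified_split(y_all[sub], split_spec)
            _, res = train_and_evaluate(
                x_all[sub], y_all[sub], cfg,
                _mode_masks(mode, snp_gene, gene_graph), split, seed=seed,
            )
            rows.append({"size": size, "seed": seed, "auc": res.auc})
            log.info("sweep size=%d seed=%d auc=%.4f", size, seed, res.auc)
    return pd.DataFrame(rows)
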