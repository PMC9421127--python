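"""SNP-gene-phenotype pathway scores from a trained model.

For every SNP-gene pair wired in the eQTL mask A, the pathway score is

    PS(s, g) = |W0 ⊙ A|[s, g] * D[g]

where D[g] is gene g's downstream influence on the positive (disease) output:
the g-th entry of the absolute-valued product of all weight matrices after the
SNP->gene layer, collapsed to the positive-class column. Pairs with no eQTL
edge have PS = 0 and are excluded; scores are deliberately NOT normalized (PS
is a product of weights on two sides of the gene layer, and normalization
would distort their relative contribution), so PS scales linearly with W0.

A ``two_layer`` variant stops the downstream product at the gene-gene layer
(D[g] = row sum of |W1 ⊙ A'|); a ``signed`` variant skips the absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelState, _effective_weight

__all__ = ["PathwayScoreTable", "pathway_scores", "top_k", "precision_at_k"]

TIE_RULE = "ties broken by (snp_id, gene_id) lexicographic order"


@dataclass
class PathwayScoreTable:
    """Rows (snp_id, gene_id, ps) sorted by ps descending."""

    rows: list[tuple[str, str, float]]
    tie_rule: str = TIE_RULE

    def __post_init__(self) -> None:
        ps = [r[2] for r in self.rows]
        if any(ps[i] < ps[i + 1] for i in range(len(ps) - 1)):
            raise ValueError("pathway table must be sorted by PS descending")

    def __len__(self) -> int:
        return len(self.rows)

    def pairs(self) -> list[tuple[str, str]]:
        return [(s, g) for s, g, _ in self.rows]


def pathway_scores(
    state: ModelState,
    variant: str = "full",
    signed: bool = False,
) -> PathwayScoreTable:
    """Score every wired SNP-gene pair and return the ranked table.

    Requires a model whose SNP->gene layer is eQTL-masked (modes gednn and
    e_dnn); the mask defines which pairs exist. ``variant='two_layer'`` uses
    only the gene-gene layer for the downstream factor; ``signed=True`` keeps
    weight signs (scores may then cancel).
    """
    cfg = state.config
    if not cfg.has_gene_layer:
        raise ValueError(f"mode {cfg.mode!r} has no gene layer; pathway scores undefined")
    if state.layer_masks[0] is None:
        raise ValueError(
            f"mode {cfg.mode!r} has a dense SNP->gene layer; pathway scores need the eQTL mask"
        )
    if state.snp_ids is None or state.gene_ids is None:
        raise ValueError("model state carries no SNP/gene ids")
    mag = (lambda w: w) if signed else np.abs
    w0 = mag(_effective_weight(state, 0))  # (p, q)
    if variant == "full":
        down = mag(_effective_weight(state, 1))
        for l in range(2, state.n_layers):
            down = down @ mag(_effective_weight(state, l))
        influence = down[:, 1]  # positive-class column
    elif variant == "two_layer":
        influence = mag(_effective_weight(state, 1)).sum(axis=1)
    else:
        raise ValueError(f"unknown pathway score variant {variant!r}")

    ps = w0 * influence[np.newaxis, :]
    mask = state.layer_masks[0]
    rows = [
        (state.snp_ids[i], state.gene_ids[j], float(ps[i, j]))
        for i, j in zip(*np.nonzero(mask))
        if ps[i, j] != 0.0
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return PathwayScoreTable(rows)


def top_k(table: PathwayScoreTable, k: int) -> PathwayScoreTable:
    """First k rows under the lexicographic tie rule; k beyond the table
    returns everything."""
    if k <= 0:
        raise ValueError("k must be at least 1")
    return PathwayScoreTable(table.rows[:k], table.tie_rule)


def precision_at_k(
    table: PathwayScoreTable, truth_pairs: set[tuple[str, str]], k: int
) -> float:
    """Fraction of the top-k ranked pairs that are in the truth set."""
    top = top_k(table, k).pairs()
    if not top:
        return 0.0
    return sum(1 for pair in top if pair in truth_pairs) / len(top)
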