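"""Binary adjacency masks for the sparse network layers.

``SnpGeneMask`` holds A (p SNPs x q genes): A[i,j] = 1 when an eQTL pair links
SNP i to gene j, or — when position tables are supplied — when the SNP lies
within ``window_bp`` of the gene's interval on the same chromosome (cis
co-location). ``GeneGraphMask`` holds A' (q x q): symmetric PPI adjacency with
a unit diagonal so each gene node feeds its own downstream unit.

SNPs linked to no gene and genes linked to no SNP are pruned, so every mask
row and column is nonzero; gene order is lexicographic for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import EdgeList, PositionTable

__all__ = [
    "SnpGeneMask",
    "GeneGraphMask",
    "build_snp_gene_mask",
    "build_gene_graph_mask",
    "build_masks",
    "mask_stats",
]

log = logging.getLogger(__name__)


@dataclass
class SnpGeneMask:
    matrix: np.ndarray  # float64 binary, (p, q)
    snp_ids: list[str]
    gene_ids: list[str]
    pruned_snps: list[str] = field(default_factory=list)
    pruned_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.snp_ids), len(self.gene_ids)):
            raise ValueError("mask shape inconsistent with id lists")
        if not np.isin(self.matrix, [0.0, 1.0]).all():
            raise ValueError("mask entries must be binary")
        if len(self.snp_ids) == 0 or len(self.gene_ids) == 0:
            raise ValueError("no SNP-gene links")
        if (self.matrix.sum(axis=1) == 0).any() or (self.matrix.sum(axis=0) == 0).any():
            raise ValueError("mask contains an all-zero row or column; prune first")


@dataclass
class GeneGraphMask:
    matrix: np.ndarray  # float64 binary, (q, q), symmetric, unit diagonal
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        q = len(self.gene_ids)
        if self.matrix.shape != (q, q):
            raise ValueError("gene graph mask must be square over gene_ids")
        if not np.isin(self.matrix, [0.0, 1.0]).all():
            raise ValueError("mask entries must be binary")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("gene graph mask must be symmetric")
        if not (np.diag(self.matrix) == 1.0).all():
            raise ValueError("gene graph mask must have a unit diagonal")


def build_snp_gene_mask(
    eqtl: EdgeList,
    snp_ids: Sequence[str],
    positions: tuple[PositionTable, PositionTable] | None = None,
    window_bp: int = 1_000_000,
) -> SnpGeneMask:
    """Assemble A from eQTL pairs, optionally augmented by positional links.

    ``positions`` is ``(snp_positions, gene_positions)``; a positional link is
    created when SNP and gene share a chromosome and the SNP coordinate falls
    within ``window_bp`` of the gene interval. Edge duplication is irrelevant
    (set semantics). Unlinked SNPs and genes are pruned and reported.
    """
    if eqtl.kind != "snp_gene":
        raise ValueError("eqtl edge list must have kind 'snp_gene'")
    snp_ids = list(snp_ids)
    snp_set = set(snp_ids)
    pairs = {(a, b) for a, b in eqtl.edges if a in snp_set}

    if positions is not None:
        snp_pos, gene_pos = positions
        sp = snp_pos.records
        sp = sp[sp["id"].isin(snp_set)]
        for _, gene in gene_pos.records.iterrows():
            on_chrom = sp[sp["chrom"] == gene["chrom"]]
            lo, hi = gene["start"] - window_bp, gene["end"] + window_bp
            hits = on_chrom[(on_chrom["start"] >= lo) & (on_chrom["start"] <= hi)]
            for sid in hits["id"]:
                pairs.add((sid, gene["id"]))

    if not pairs:
        raise ValueError("no SNP-gene links")
    gene_ids = sorted({b for _, b in pairs})
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    matrix = np.zeros((len(snp_ids), len(gene_ids)))
    for a, b in pairs:
        matrix[snp_index[a], gene_index[b]] = 1.0

    keep_rows = matrix.sum(axis=1) > 0
    pruned_snps = [s for s, k in zip(snp_ids, keep_rows) if not k]
    if pruned_snps:
        log.info("pruned %d SNPs with no gene link", len(pruned_snps))
    matrix = matrix[keep_rows]
    kept_snps = [s for s, k in zip(snp_ids, keep_rows) if k]
    # gene columns are nonzero by construction (genes only enter via pairs)
    return SnpGeneMask(matrix, kept_snps, gene_ids, pruned_snps=pruned_snps)


def build_gene_graph_mask(ppi: EdgeList, gene_ids: Sequence[str]) -> GeneGraphMask:
    """Assemble A' over the retained genes: symmetric PPI edges plus a unit
    diagonal; edges touching unretained genes are dropped with a logged count."""
    if ppi.kind != "gene_gene":
        raise ValueError("ppi edge list must have kind 'gene_gene'")
    gene_ids = list(gene_ids)
    index = {g: j for j, g in enumerate(gene_ids)}
    matrix = np.eye(len(gene_ids))
    dropped = 0
    for a, b in ppi.edges:
        if a in index and b in index:
            matrix[index[a], index[b]] = 1.0
            matrix[index[b], index[a]] = 1.0
        else:
            dropped += 1
    if dropped:
        log.info("dropped %d PPI edges to unretained genes", dropped)
    return GeneGraphMask(matrix, gene_ids)


def build_masks(
    eqtl: EdgeList,
    ppi: EdgeList,
    snp_ids: Sequence[str],
    positions: tuple[PositionTable, PositionTable] | None = None,
    window_bp: int = 1_000_000,
    strict: bool = False,
) -> tuple[SnpGeneMask, GeneGraphMask]:
    """Build both masks jointly.

    Default (permissive) mode keeps every gene with at least one SNP link —
    the self-loop on the diagonal of A' suffices for gene-layer membership.
    ``strict`` mode additionally prunes genes with no off-diagonal PPI edge
    (gene layer keeps only genes related to both a SNP and another gene) and
    rebuilds A restricted to the surviving genes.
    """
    a = build_snp_gene_mask(eqtl, snp_ids, positions=positions, window_bp=window_bp)
    a_prime = build_gene_graph_mask(ppi, a.gene_ids)
    if strict:
        off_diag = a_prime.matrix - np.eye(len(a.gene_ids))
        connected = off_diag.sum(axis=1) > 0
        if not connected.any():
            raise ValueError("strict mode: no gene has an off-diagonal PPI edge")
        kept_genes = [g for g, k in zip(a.gene_ids, connected) if k]
        pruned = [g for g, k in zip(a.gene_ids, connected) if not k]
        restricted = EdgeList(
            [(s, g) for s, g in eqtl.edges if g in set(kept_genes)], "snp_gene"
        )
        pos = positions
        if pos is not None:
            gp = pos[1].records
            pos = (pos[0], PositionTable(gp[gp["id"].isin(set(kept_genes))].reset_index(drop=True)))
        a = build_snp_gene_mask(restricted, snp_ids, positions=pos, window_bp=window_bp)
        a.pruned_genes = pruned
        a_prime = build_gene_graph_mask(ppi, a.gene_ids)
        log.info("strict mode pruned %d genes lacking PPI edges", len(pruned))
    return a, a_prime


def mask_stats(mask: SnpGeneMask | GeneGraphMask) -> dict:
    """Density, degree distributions, and pruning counts for a mask."""
    m = mask.matrix
    stats = {
        "shape": m.shape,
        "density": float(m.mean()),
        "row_degrees": m.sum(axis=1).astype(int).tolist(),
        "col_degrees": m.sum(axis=0).astype(int).tolist(),
    }
    if isinstance(mask, SnpGeneMask):
        stats["n_pruned_snps"] = len(mask.pruned_snps)
        stats["n_pruned_genes"] = len(mask.pruned_genes)
    return stats
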