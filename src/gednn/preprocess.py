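"""SNP quality-control filters and imputation.

The pipeline order is fixed: missing-rate filter -> imputation -> MAF filter.
Per-SNP missing fraction strictly greater than ``max_missing_rate`` (default
20%) drops the SNP; surviving missing entries are imputed (column mode or
rounded column mean); SNPs are then kept only if the minor allele frequency
MAF = min(f, 1-f), with f = dosage sum / 2n, is strictly greater than
``maf_threshold`` (default 0.05). Both strict inequalities are deliberate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import EdgeList, GenotypeMatrix, LabelVector

__all__ = [
    "PreprocessConfig",
    "filter_missing",
    "impute",
    "filter_maf",
    "harmonize_ids",
    "run_preprocess",
    "maf",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    max_missing_rate: float = 0.20
    maf_threshold: float = 0.05
    impute_strategy: Literal["mode", "mean"] = "mode"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.impute_strategy not in ("mode", "mean"):
            raise ValueError(f"unknown impute strategy {self.impute_strategy!r}")


def filter_missing(g: GenotypeMatrix, max_missing_rate: float = 0.20) -> GenotypeMatrix:
    """Drop SNP columns whose missing fraction exceeds ``max_missing_rate``.

    The boundary is kept: a column missing exactly the threshold fraction
    survives. Column order is preserved and surviving columns are returned
    unchanged.
    """
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    frac = g.missing.mean(axis=0)
    keep = frac <= max_missing_rate
    if not keep.any():
        raise ValueError("no SNPs survive missing-rate filter")
    kept_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    log.info("missing-rate filter: kept %d / %d SNPs", keep.sum(), g.n_snps)
    return g.subset_snps(kept_ids)


def impute(g: GenotypeMatrix, strategy: Literal["mode", "mean"] = "mode") -> GenotypeMatrix:
    """Fill missing calls per SNP column.

    ``mode`` fills the most frequent observed call (ties broken toward the
    smaller call value); ``mean`` fills the observed column mean rounded to the
    nearest legal call with round-half-to-even at .5 ties.
    """
    if not g.missing.any():
        return g
    calls = g.calls.copy()
    for c in range(g.n_snps):
        miss = g.missing[:, c]
        if not miss.any():
            continue
        observed = calls[~miss, c]
        if observed.size == 0:
            raise ValueError(f"SNP {g.snp_ids[c]!r} has no observed calls to impute from")
        if strategy == "mode":
            counts = np.bincount(observed, minlength=3)
            fill = int(np.argmax(counts))  # argmax takes the smallest tied call
        elif strategy == "mean":
            # numpy rounds half to even, keeping the {0,1,2} invariant
            fill = int(np.clip(np.round(observed.mean()), 0, 2))
        else:
            raise ValueError(f"unknown impute strategy {strategy!r}")
        calls[miss, c] = fill
    return GenotypeMatrix(
        calls, np.zeros_like(g.missing), list(g.snp_ids), list(g.sample_ids)
    )


def maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency min(f, 1-f), f = dosage sum / 2n."""
    if g.missing.any():
        raise ValueError("MAF is computed after imputation; missing calls present")
    f = g.calls.sum(axis=0, dtype=float) / (2.0 * g.n_samples)
    return np.minimum(f, 1.0 - f)


def filter_maf(g: GenotypeMatrix, maf_threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly greater than ``maf_threshold``."""
    keep = maf(g) > maf_threshold
    if not keep.any():
        raise ValueError("no SNPs survive MAF filter")
    kept_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    log.info("MAF filter: kept %d / %d SNPs", keep.sum(), g.n_snps)
    return g.subset_snps(kept_ids)


def harmonize_ids(
    g: GenotypeMatrix,
    labels: LabelVector,
    snp_gene: EdgeList | None = None,
    ppi: EdgeList | None = None,
) -> tuple[GenotypeMatrix, LabelVector, EdgeList | None, EdgeList | None]:
    """Restrict samples to the genotype/label intersection and drop eQTL edges
    whose SNP is absent from the genotype matrix; counts of everything dropped
    are logged."""
    label_set = set(labels.sample_ids)
    shared = [s for s in g.sample_ids if s in label_set]
    if not shared:
        raise ValueError("no samples shared between genotypes and labels")
    dropped_samples = (g.n_samples - len(shared)) + (len(labels.sample_ids) - len(shared))
    g2 = g.subset_samples(shared) if len(shared) < g.n_samples else g
    labels2 = labels.subset(shared)

    snp_set = set(g.snp_ids)
    snp_gene2 = snp_gene
    n_edge_dropped = 0
    if snp_gene is not None:
        kept = [(a, b) for a, b in snp_gene.edges if a in snp_set]
        n_edge_dropped = len(snp_gene.edges) - len(kept)
        snp_gene2 = EdgeList(kept, snp_gene.kind) if n_edge_dropped else snp_gene
    log.info(
        "harmonize: %d samples retained (%d dropped), %d eQTL edges dropped",
        len(shared), dropped_samples, n_edge_dropped,
    )
    return g2, labels2, snp_gene2, ppi


def run_preprocess(
    g: GenotypeMatrix, config: PreprocessConfig | None = None
) -> GenotypeMatrix:
    """missing-rate filter -> impute -> MAF filter, in that order."""
    config = config or PreprocessConfig()
    g = filter_missing(g, config.max_missing_rate)
    g = impute(g, config.impute_strategy)
    return filter_maf(g, config.maf_threshold)
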