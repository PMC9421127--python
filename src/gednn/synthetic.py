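"""Coupled synthetic genotype / eQTL / PPI / phenotype generator.

The layers are generated jointly, not independently: binary phenotypes arise
from planted SNP -> gene -> phenotype paths that run through the same SNP-gene
and gene-gene edge sets the model later uses as masks, so the classification
signal and the graph structure agree by construction.

Generative story (liability-threshold model):

1. Per SNP, a minor-allele frequency f ~ U(maf_range); dosages ~ Binomial(2, f).
2. A sparse bipartite SNP-gene edge set at ``snp_gene_density`` (every SNP is
   guaranteed at least one edge) and a sparse symmetric gene-gene (PPI) edge
   set at ``ppi_density``.
3. ``n_causal_paths`` SNP-gene edges are planted as causal, with their target
   genes grown as a connected neighborhood (module) of the PPI graph: complex
   disease genes act cumulatively through the gene network rather than in
   isolation, so the planted genes cluster instead of scattering uniformly.
   A gene's activity is ``effect_size`` times the summed dosages of its causal
   SNPs, plus a one-step propagation over PPI edges at half weight, plus
   Gaussian noise.
4. The liability is the sum of causal-gene activities; the intercept is set to
   minus the sample median so prevalence is ~0.5 (mirroring the near-balanced
   case/control cohorts this class of study works with); label = liability > 0.
5. Calls are masked missing uniformly at ``missing_rate``.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    EdgeList,
    GenotypeMatrix,
    LabelVector,
    write_edge_list,
    write_genotypes,
    write_labels,
)

__all__ = ["SimConfig", "SimTruth", "simulate", "write_dataset", "read_truth"]

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_samples: int = 500
    n_snps: int = 1000
    n_genes: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_gene_density: float = 0.01
    ppi_density: float = 0.05
    n_causal_paths: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("snp_gene_density", "ppi_density"):
            d = getattr(self, name)
            if not 0.0 < d <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.n_samples, self.n_snps, self.n_genes) < 1:
            raise ValueError("n_samples, n_snps, n_genes must be positive")
        if self.n_causal_paths < 0:
            raise ValueError("n_causal_paths must be nonnegative")


@dataclass
class SimTruth:
    """Planted ground truth for recovery benchmarks."""

    causal_pairs: list[tuple[str, str]]
    causal_effects: list[float]
    liability_intercept: float = 0.0


def _snp_id(i: int) -> str:
    return f"rs{i + 1}"


def _gene_id(j: int) -> str:
    return f"g{j + 1:03d}"


def simulate(
    config: SimConfig,
) -> tuple[GenotypeMatrix, LabelVector, EdgeList, EdgeList, SimTruth]:
    """Draw one coupled dataset; byte-identical across runs at a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p, q = cfg.n_samples, cfg.n_snps, cfg.n_genes
    snp_ids = [_snp_id(i) for i in range(p)]
    gene_ids = [_gene_id(j) for j in range(q)]

    # genotypes: per-SNP binomial dosages at a uniform MAF
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    calls = rng.binomial(2, maf[np.newaxis, :], size=(n, p)).astype(np.int8)

    # bipartite SNP-gene edges; repair SNPs the density draw left unlinked
    adj = rng.random((p, q)) < cfg.snp_gene_density
    unlinked = np.flatnonzero(adj.sum(axis=1) == 0)
    for i in unlinked:
        adj[i, rng.integers(q)] = True
    if len(unlinked):
        log.info("added one edge for %d SNPs left unlinked by the density draw", len(unlinked))
    edge_idx = np.argwhere(adj)
    snp_gene = EdgeList(
        [(snp_ids[i], gene_ids[j]) for i, j in edge_idx], "snp_gene"
    )

    # symmetric PPI edges over gene pairs
    upper = np.triu(rng.random((q, q)) < cfg.ppi_density, k=1)
    ppi_adj = upper | upper.T
    ppi = EdgeList(
        [(gene_ids[i], gene_ids[j]) for i, j in np.argwhere(upper)], "gene_gene"
    )

    # plant causal SNP->gene paths whose target genes form a PPI module:
    # grow a connected neighborhood gene by gene until the edges feeding it
    # can host all requested paths (restarting on exhausted components)
    if cfg.n_causal_paths > len(edge_idx):
        raise ValueError(
            f"n_causal_paths={cfg.n_causal_paths} exceeds the {len(edge_idx)} generated edges"
        )
    n_causal = cfg.n_causal_paths
    chosen = np.array([], dtype=int)
    if n_causal > 0:
        edges_by_gene = [np.flatnonzero(adj[:, j]) for j in range(q)]
        cluster: list[int] = []
        in_cluster = np.zeros(q, dtype=bool)
        frontier: list[int] = []
        n_available = 0
        while n_available < n_causal:
            if not frontier:
                rest = np.flatnonzero(~in_cluster)
                frontier = [int(rng.choice(rest))]  # new module seed
                in_cluster[frontier[0]] = True
            g = frontier.pop(0)
            cluster.append(g)
            n_available += len(edges_by_gene[g])
            nbrs = np.flatnonzero(ppi_adj[g] & ~in_cluster)
            nbrs = rng.permutation(nbrs)
            in_cluster[nbrs] = True
            frontier.extend(int(v) for v in nbrs)
        candidates = np.flatnonzero(np.isin(edge_idx[:, 1], cluster))
        chosen = rng.choice(candidates, size=n_causal, replace=False)
    causal_pairs = [(snp_ids[i], gene_ids[j]) for i, j in edge_idx[chosen]]

    # gene activity: causal dosage sums + one-step PPI propagation + noise
    causal_w = np.zeros((p, q))
    for i, j in edge_idx[chosen]:
        causal_w[i, j] = cfg.effect_size
    activity = calls.astype(np.float64) @ causal_w
    activity = activity + (cfg.effect_size / 2.0) * (activity @ ppi_adj.astype(np.float64))
    activity += rng.normal(0.0, cfg.noise_sd, size=activity.shape)

    causal_gene_cols = sorted({j for _, j in edge_idx[chosen]})
    liability = activity[:, causal_gene_cols].sum(axis=1) if causal_gene_cols else (
        rng.normal(0.0, max(cfg.noise_sd, 1e-12), size=n)
    )
    intercept = -float(np.median(liability))
    labels = (liability + intercept > 0).astype(np.int8)

    # uniform missingness
    missing = rng.random((n, p)) < cfg.missing_rate
    geno = GenotypeMatrix(np.where(missing, 0, calls), missing, snp_ids,
                          [f"s{i + 1:04d}" for i in range(n)])
    label_vec = LabelVector(labels, list(geno.sample_ids))
    truth = SimTruth(
        causal_pairs=causal_pairs,
        causal_effects=[cfg.effect_size] * n_causal,
        liability_intercept=intercept,
    )
    return geno, label_vec, snp_gene, ppi, truth


def write_dataset(
    geno: GenotypeMatrix,
    labels: LabelVector,
    snp_gene: EdgeList,
    ppi: EdgeList,
    truth: SimTruth,
    directory: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write the full dataset in the delimited-text dialects plus a truth TSV.

    Refuses a non-empty existing directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (pass force=True to overwrite)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.tsv",
        "labels": directory / "labels.tsv",
        "eqtl": directory / "eqtl_pairs.tsv",
        "ppi": directory / "ppi_edges.tsv",
        "truth": directory / "truth.tsv",
    }
    write_genotypes(geno, paths["genotypes"])
    write_labels(labels, paths["labels"])
    write_edge_list(snp_gene, paths["eqtl"])
    write_edge_list(ppi, paths["ppi"])
    with open(paths["truth"], "w") as fh:
        fh.write("snp_id\tgene_id\teffect\n")
        for (s, g), e in zip(truth.causal_pairs, truth.causal_effects):
            fh.write(f"{s}\t{g}\t{e!r}\n")
    return paths


def read_truth(path: str | Path) -> SimTruth:
    pairs, effects = [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            s, g, e = line.split()
            pairs.append((s, g))
            effects.append(float(e))
    return SimTruth(pairs, effects)
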