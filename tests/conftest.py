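import numpy as np
import pytest

import gednn as G


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small coupled dataset plus masks, shared across fast tests."""
    cfg = G.SimConfig(n_samples=120, n_snps=60, n_genes=12, seed=11)
    geno, labels, eqtl, ppi, truth = G.simulate(cfg)
    clean = G.run_preprocess(geno)
    clean, labels, eqtl, ppi = G.harmonize_ids(clean, labels, eqtl, ppi)
    a, a_prime = G.build_masks(eqtl, ppi, clean.snp_ids)
    return {
        "config": cfg,
        "geno": clean.subset_snps(a.snp_ids),
        "labels": labels,
        "eqtl": eqtl,
        "ppi": ppi,
        "snp_gene": a,
        "gene_graph": a_prime,
        "truth": truth,
    }


@pytest.fixture
def fast_model_config():
    """Short training budget for smoke-level fits."""
    def make(mode="gednn", **kw):
        kw.setdefault("max_epochs", 5)
        kw.setdefault("patience", 0)
        return G.ModelConfig(mode=mode, **kw)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(123)
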