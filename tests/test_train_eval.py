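import numpy as np
import pytest

import gednn as G
from gednn.io_formats import LabelVector
from gednn.train_eval import (
    SplitSpec,
    roc_auc,
    run_comparison,
    sample_size_sweep,
    stratified_split,
    stratified_subsample,
)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney with ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_balanced_counting_oracle(self):
        y = LabelVector(np.repeat([0, 1], 50), [f"s{i}" for i in range(100)])
        tr, va, te = stratified_split(y, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        for idx, expect in zip((tr, va, te), (40, 5, 5)):
            assert y.labels[idx].sum() == expect

    def test_disjoint_and_exhaustive(self):
        y = np.r_[np.zeros(33), np.ones(27)].astype(int)
        tr, va, te = stratified_split(y, SplitSpec(seed=3))
        combined = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(combined, np.arange(60))

    def test_proportions_within_one_sample(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 157)
        global_prop = y.mean()
        for idx in stratified_split(y, SplitSpec(seed=1)):
            n_pos = y[idx].sum()
            assert abs(n_pos - global_prop * len(idx)) <= 1.0

    def test_deterministic_under_seed(self):
        y = np.repeat([0, 1], 30)
        a = stratified_split(y, SplitSpec(seed=9))
        b = stratified_split(y, SplitSpec(seed=9))
        for i, j in zip(a, b):
            np.testing.assert_array_equal(i, j)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            stratified_split(np.zeros(20, dtype=int), SplitSpec())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(0.8, 0.1, 0.2)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.0, 0.0, 1.0, 1.0]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc(np.full(10, 0.3), np.repeat([0, 1], 5))
        assert auc == pytest.approx(0.5)

    def test_worked_example(self):
        auc, _ = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_matches_brute_force_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc, _ = roc_auc(scores, y)
            assert auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_auc_equals_trapezoid_of_roc_points(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        scores = rng.random(40)
        auc, points = roc_auc(scores, y)
        assert auc == pytest.approx(np.trapezoid(points[:, 1], points[:, 0]), abs=1e-9)
        assert (np.diff(points[:, 0]) >= 0).all() and (np.diff(points[:, 1]) >= 0).all()

    def test_one_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestRunComparison:
    def test_four_modes_share_split_and_only_masking_differs(self, tiny_dataset):
        d = tiny_dataset
        configs = {
            m: G.ModelConfig(mode=m, hidden_widths=(8, 4), max_epochs=3, patience=0, seed=0)
            for m in ("dnn", "e_dnn", "gedfn", "gednn")
        }
        results = run_comparison(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                                 configs=configs, seed=0)
        assert [r.mode for r in results] == ["dnn", "e_dnn", "gedfn", "gednn"]
        assert len({(r.n_train, r.n_test) for r in results}) == 1

    def test_rerun_reproduces_aucs_exactly(self, tiny_dataset):
        d = tiny_dataset
        configs = {"gednn": G.ModelConfig(mode="gednn", max_epochs=3, patience=0, seed=0)}
        r1 = run_comparison(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                            configs=configs, modes=("gednn",), seed=0)
        r2 = run_comparison(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                            configs=configs, modes=("gednn",), seed=0)
        assert r1[0].auc == r2[0].auc

    def test_mode_config_mismatch_rejected(self, tiny_dataset):
        d = tiny_dataset
        with pytest.raises(ValueError, match="mode"):
            run_comparison(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                           configs={"dnn": G.ModelConfig(mode="gednn")}, modes=("dnn",))


class TestSubsampling:
    def test_proportion_preserved_at_every_size(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(120), np.ones(80)].astype(int)
        for size in (150, 100, 50, 20):
            idx = stratified_subsample(y, size, rng)
            assert len(idx) == size
            assert abs(y[idx].sum() - 0.4 * size) <= 1.0

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_subsample(np.repeat([0, 1], 5), 11, rng)

    def test_sweep_size_below_twice_batch_rejected(self, tiny_dataset):
        d = tiny_dataset
        with pytest.raises(ValueError, match="twice the batch size"):
            sample_size_sweep(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                              sizes=(10,), seeds=(0,),
                              config=G.ModelConfig(mode="gednn", batch_size=8))

    def test_sweep_returns_tidy_table(self, tiny_dataset):
        d = tiny_dataset
        cfg = G.ModelConfig(mode="gednn", max_epochs=2, patience=0)
        table = sample_size_sweep(d["geno"], d["labels"], d["snp_gene"], d["gene_graph"],
                                  sizes=(100, 60), seeds=(0, 1), config=cfg)
        assert set(table.columns) == {"size", "seed", "auc"}
        assert len(table) == 4
        assert table["auc"].between(0, 1).all()
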