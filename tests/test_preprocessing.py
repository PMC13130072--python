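"""Normalization, per-batch scaling and the HVG/LVG split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scges import (
    RawBatch,
    RawBatchCollection,
    normalize_log,
    prepare_dataset,
    select_hvgs,
    zscore_per_batch,
)


class TestNormalizeLog:
    @pytest.mark.parametrize(
        "count, lib, expected",
        [
            (0, 5000.0, 0.0),
            (2, 20000.0, np.log(2.0)),
        ],
    )
    def test_scalar_values(self, count, lib, expected):
        out = normalize_log(np.array([[count]]), np.array([lib]))
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_row_example(self):
        # ln(1 + 1e4 * c / l) evaluated by hand for c=[1,3], l=4
        out = normalize_log(np.array([[1, 3]]), np.array([4.0]))
        np.testing.assert_allclose(
            out[0], [np.log(2501.0), np.log(7501.0)], rtol=1e-12
        )
        assert out[0, 0] == pytest.approx(7.82444, abs=1e-5)
        assert out[0, 1] == pytest.approx(8.92279, abs=1e-5)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            normalize_log(np.array([[-1]]), np.array([10.0]))
        with pytest.raises(ValueError):
            normalize_log(np.array([[0.5]]), np.array([10.0]))

    def test_rejects_zero_library_with_counts(self):
        with pytest.raises(ValueError):
            normalize_log(np.array([[3]]), np.array([0.0]))

    def test_all_zero_cell_allowed(self):
        out = normalize_log(np.array([[0, 0]]), np.array([0.0]))
        np.testing.assert_array_equal(out, 0.0)

    @given(
        c1=st.integers(0, 1000),
        c2=st.integers(0, 1000),
        lib=st.floats(1.0, 1e6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_counts(self, c1, c2, lib):
        lo, hi = sorted((c1, c2))
        out = normalize_log(np.array([[lo], [hi]]), np.array([lib, lib]))
        assert out[0, 0] <= out[1, 0]


class TestZscorePerBatch:
    def test_hand_computed(self):
        # mean 2, population sd sqrt(2/3)
        out, _ = zscore_per_batch(
            np.array([[1.0], [2.0], [3.0]]), np.zeros(3, dtype=int)
        )
        np.testing.assert_allclose(
            out[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_gene_zeroed(self):
        out, _ = zscore_per_batch(np.full((4, 2), 7.0), np.zeros(4, dtype=int))
        np.testing.assert_array_equal(out, 0.0)

    def test_per_batch_moments(self, rng):
        x = rng.normal(2.0, 3.0, size=(40, 6))
        bids = np.repeat([0, 1], 20)
        out, stats = zscore_per_batch(x, bids)
        for b in (0, 1):
            blk = out[bids == b]
            np.testing.assert_allclose(blk.mean(axis=0), 0.0, atol=1e-6)
            np.testing.assert_allclose(blk.std(axis=0), 1.0, atol=1e-6)
        assert set(stats) == {0, 1}

    def test_idempotent(self, rng):
        x = rng.normal(size=(30, 5))
        bids = np.repeat([0, 1], 15)
        once, _ = zscore_per_batch(x, bids)
        twice, _ = zscore_per_batch(once, bids)
        np.testing.assert_allclose(once, twice, atol=1e-6)

    def test_single_cell_batch_rejected(self):
        with pytest.raises(ValueError, match="1"):
            zscore_per_batch(np.ones((3, 2)), np.array([0, 0, 1]))


class TestSelectHvgs:
    def test_recovers_planted_variable_genes(self, rng):
        # 10 marker-like genes swing 8x between two cell groups, with
        # baselines spread over a realistic mean range, against 190
        # constant background genes; the 10 must occupy the HVG set
        n = 200
        base = np.exp(rng.normal(np.log(5.0), 1.0, size=190))
        levels = np.exp(np.linspace(np.log(1.0), np.log(25.0), 10))
        means = np.tile(np.concatenate([levels, base]), (n, 1))
        group = np.arange(n) % 2
        for j in range(10):
            means[:, j] = np.where(group == j % 2, levels[j], 8 * levels[j])
        counts = rng.poisson(means)
        normed = normalize_log(counts, counts.sum(axis=1).astype(float))
        hvg, lvg = select_hvgs(normed, np.repeat([0, 1], n // 2), n_top=10)
        assert set(hvg) == set(range(10))
        assert len(lvg) == 190

    def test_invalid_n_top(self, rng):
        normed = rng.normal(size=(10, 5))
        for bad in (0, 5, 6):
            with pytest.raises(ValueError):
                select_hvgs(normed, np.repeat([0, 1], 5), n_top=bad)

    def test_deterministic(self, rng):
        normed = np.abs(rng.normal(size=(60, 30)))
        bids = np.repeat([0, 1, 2], 20)
        h1, l1 = select_hvgs(normed, bids, n_top=10)
        h2, l2 = select_hvgs(normed, bids, n_top=10)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(l1, l2)

    def test_partition_is_exact(self, rng):
        normed = np.abs(rng.normal(size=(40, 25)))
        hvg, lvg = select_hvgs(normed, np.repeat([0, 1], 20), n_top=7)
        assert len(hvg) == 7
        assert len(np.intersect1d(hvg, lvg)) == 0
        assert len(hvg) + len(lvg) == 25


def _make_collection(rng, genes_a, genes_b, labels=False):
    ca = rng.integers(0, 6, size=(8, len(genes_a)))
    cb = rng.integers(0, 6, size=(10, len(genes_b)))
    mk = lambda n, p: np.array([f"{p}{i}" for i in range(n)], dtype=object)
    la = mk(8, "la_") if labels else None
    lb = mk(10, "lb_") if labels else None
    return RawBatchCollection(
        batches=[
            RawBatch(ca, mk(8, "a"), np.array(genes_a, dtype=object), la),
            RawBatch(cb, mk(10, "b"), np.array(genes_b, dtype=object), lb),
        ],
        batch_names=["A", "B"],
    )


class TestPrepareDataset:
    def test_gene_intersection_and_order(self, rng):
        genes_a = [f"g{i}" for i in range(100)]
        genes_b = [f"g{i}" for i in range(20, 120)]
        data = prepare_dataset(_make_collection(rng, genes_a, genes_b), n_top=5)
        assert data.n_genes == 80
        assert list(data.gene_ids) == [f"g{i}" for i in range(20, 100)]

    def test_single_batch_onehot(self, rng):
        genes = [f"g{i}" for i in range(30)]
        raw = RawBatchCollection(
            batches=[
                RawBatch(
                    rng.integers(0, 5, size=(12, 30)),
                    np.array([f"c{i}" for i in range(12)], dtype=object),
                    np.array(genes, dtype=object),
                )
            ],
            batch_names=["only"],
        )
        data = prepare_dataset(raw, n_top=5)
        np.testing.assert_array_equal(data.batch_onehot, np.ones((12, 1)))

    def test_duplicate_gene_ids_rejected(self, rng):
        genes = ["g0", "g1", "g1", "g2"]
        with pytest.raises(ValueError, match="duplicated"):
            prepare_dataset(_make_collection(rng, genes, genes), n_top=2)

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ValueError):
            prepare_dataset(
                _make_collection(rng, ["a1", "a2"], ["b1", "b2"]), n_top=1
            )

    def test_invariants_on_fixture(self, prepared):
        data = prepared
        # partition
        assert len(data.hvg_index) + len(data.lvg_index) == data.n_genes
        assert len(np.intersect1d(data.hvg_index, data.lvg_index)) == 0
        # one-hot rows
        np.testing.assert_array_equal(data.batch_onehot.sum(axis=1), 1.0)
        # per-batch scaling contract (constant genes are zeroed)
        for b in range(data.n_batches):
            blk = data.X_scale[data.batch_ids == b]
            sd = blk.std(axis=0)
            live = sd > 0.5
            np.testing.assert_allclose(blk[:, live].mean(axis=0), 0, atol=1e-6)
            np.testing.assert_allclose(sd[live], 1.0, atol=1e-6)
        # library sizes are count row sums over the shared gene set
        np.testing.assert_allclose(data.lib_sizes, data.counts.sum(axis=1))

    def test_cell_permutation_equivariance(self, rng):
        genes = [f"g{i}" for i in range(40)]
        raw = _make_collection(rng, genes, genes, labels=True)
        data = prepare_dataset(raw, n_top=8)
        perm = rng.permutation(8)
        b0 = raw.batches[0]
        raw_p = RawBatchCollection(
            batches=[
                RawBatch(b0.counts[perm], b0.cell_ids[perm],
                         b0.gene_ids, b0.cell_labels[perm]),
                raw.batches[1],
            ],
            batch_names=["A", "B"],
        )
        data_p = prepare_dataset(raw_p, n_top=8)
        np.testing.assert_allclose(data_p.X_scale[:8], data.X_scale[:8][perm])
        np.testing.assert_allclose(data_p.X_scale[8:], data.X_scale[8:])
        np.testing.assert_array_equal(data_p.hvg_index, data.hvg_index)
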