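"""Integration training dynamics and denoised output contracts."""

import numpy as np
import pytest

from scges import (
    SCGESIntegrator,
    build_triplets,
    denoise,
    train_hvg_block,
    train_lvg_block,
)
from scges.config import TrainConfig
from scges.model import LossWeights


def _cfg(**kw):
    base = dict(epochs_hvg=6, epochs_lvg=6, minibatch_size=32,
                early_stop_patience=100, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainHvgBlock:
    def test_pure_autoencoder_loss_decreases(self, tiny_prepared):
        cfg = _cfg(weights=LossWeights(beta1=0.0, beta2=0.0))
        _, log = train_hvg_block(tiny_prepared, None, cfg)
        recon = [e["recon"] for e in log[:5]]
        assert all(b < a for a, b in zip(recon, recon[1:]))

    def test_seeded_runs_reproduce_loss(self, tiny_prepared):
        tri = build_triplets(tiny_prepared, seed=0)
        _, log1 = train_hvg_block(tiny_prepared, tri, _cfg())
        tri2 = build_triplets(tiny_prepared, seed=0)
        _, log2 = train_hvg_block(tiny_prepared, tri2, _cfg())
        assert log1[-1]["total"] == pytest.approx(log2[-1]["total"], abs=1e-6)

    def test_total_loss_descends_with_default_weights(self, tiny_prepared):
        tri = build_triplets(tiny_prepared, seed=0)
        _, log = train_hvg_block(tiny_prepared, tri, _cfg(epochs_hvg=10))
        assert log[-1]["total"] < log[0]["total"]

    def test_beta2_without_labels_rejected(self, tiny_sim):
        from scges import RawBatch, RawBatchCollection, prepare_dataset

        raw, _ = tiny_sim
        stripped = RawBatchCollection(
            [RawBatch(b.counts, b.cell_ids, b.gene_ids) for b in raw.batches],
            raw.batch_names,
        )
        data = prepare_dataset(stripped, n_top=40)
        with pytest.raises(ValueError, match="beta2"):
            train_hvg_block(data, None, _cfg(weights=LossWeights(beta1=0.0)))


class TestTrainLvgBlock:
    def test_strict_alternation_schedule(self, tiny_prepared):
        cfg = _cfg(alternating_period=1, epochs_lvg=2)
        state, _ = train_hvg_block(
            tiny_prepared, None, _cfg(weights=LossWeights(beta1=0, beta2=0),
                                      epochs_hvg=2)
        )
        _, log = train_lvg_block(tiny_prepared, state, cfg)
        phases = "".join(e["phases"] for e in log)
        assert set(phases) == {"R", "C"}
        assert all(a != b for a, b in zip(phases, phases[1:]))

    def test_missing_labels_skips_classification(self, tiny_sim, caplog):
        from scges import RawBatch, RawBatchCollection, prepare_dataset

        raw, _ = tiny_sim
        stripped = RawBatchCollection(
            [RawBatch(b.counts, b.cell_ids, b.gene_ids) for b in raw.batches],
            raw.batch_names,
        )
        data = prepare_dataset(stripped, n_top=40)
        cfg = _cfg(weights=LossWeights(beta1=0, beta2=0), epochs_hvg=2,
                   epochs_lvg=2)
        state, _ = train_hvg_block(data, None, cfg)
        with caplog.at_level("WARNING"):
            _, log = train_lvg_block(data, state, cfg)
        assert set("".join(e["phases"] for e in log)) == {"R"}
        assert any("labels" in r.message for r in caplog.records)

    def test_hvg_parameters_frozen_during_lvg_phase(self, tiny_prepared):
        cfg = _cfg(weights=LossWeights(beta1=0, beta2=0), epochs_hvg=2,
                   epochs_lvg=3)
        state, _ = train_hvg_block(tiny_prepared, None, cfg)
        before = {k: v.data.copy() for k, v in state.params().items()
                  if k.startswith("hvg.")}
        train_lvg_block(tiny_prepared, state, cfg)
        after = {k: v.data for k, v in state.params().items()
                 if k.startswith("hvg.")}
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])


class TestDenoise:
    def test_row_sums_match_block_library(self, fitted_integrator, prepared):
        res = fitted_integrator.denoise(prepared, target_batch="per-cell")
        got_h = res.denoised_counts_mean[:, prepared.hvg_index].sum(axis=1)
        np.testing.assert_allclose(got_h, prepared.block_lib("hvg"), rtol=1e-3)
        got_l = res.denoised_counts_mean[:, prepared.lvg_index].sum(axis=1)
        np.testing.assert_allclose(got_l, prepared.block_lib("lvg"), rtol=1e-3)

    def test_outputs_nonnegative_and_aligned(self, fitted_integrator, prepared):
        res = fitted_integrator.denoise(prepared)
        assert res.denoised_counts_mean.shape == prepared.counts.shape
        assert np.all(res.denoised_counts_mean >= 0)
        assert np.all(res.denoised_norm >= 0)
        assert res.z_hvg.shape[0] == prepared.n_cells

    def test_harmonized_decoding_shrinks_batch_gaps(
        self, fitted_integrator, prepared
    ):
        from scges.preprocessing import normalize_log

        res = fitted_integrator.denoise(prepared, target_batch=0)
        x_norm = normalize_log(prepared.counts, prepared.lib_sizes)

        def max_gap(m):
            gaps = []
            for b in range(3):
                for c in range(b + 1, 3):
                    gaps.append(np.abs(
                        m[prepared.batch_ids == b].mean(axis=0)
                        - m[prepared.batch_ids == c].mean(axis=0)
                    ).mean())
            return max(gaps)

        assert max_gap(res.denoised_norm) < max_gap(x_norm)

    def test_single_batch_target_is_noop(self, rng):
        from scges import RawBatch, RawBatchCollection, prepare_dataset

        counts = rng.poisson(2.0, size=(30, 50))
        labels = np.array(["a", "b", "c"] * 10, dtype=object)
        raw = RawBatchCollection(
            [RawBatch(counts, np.array([f"c{i}" for i in range(30)], dtype=object),
                      np.array([f"g{i}" for i in range(50)], dtype=object), labels)],
            ["only"],
        )
        data = prepare_dataset(raw, n_top=10)
        est = SCGESIntegrator(seed=0, beta1=0.0, epochs_hvg=3, epochs_lvg=3,
                              hidden=(16, 8), latent=4, minibatch_size=16)
        est.fit(data)
        a = est.denoise(data, target_batch=0)
        b = est.denoise(data, target_batch="per-cell")
        np.testing.assert_array_equal(a.denoised_counts_mean,
                                      b.denoised_counts_mean)

    def test_target_batch_out_of_range(self, fitted_integrator, prepared):
        with pytest.raises(ValueError, match="out of range"):
            denoise(prepared, fitted_integrator.state_, target_batch=7)


class TestEstimatorSurface:
    def test_sklearn_param_protocol(self):
        est = SCGESIntegrator(seed=3)
        params = est.get_params()
        assert params["seed"] == 3
        est.set_params(beta2=2.5)
        assert est.beta2 == 2.5

    def test_unfitted_transform_raises(self, prepared):
        with pytest.raises(RuntimeError, match="fit"):
            SCGESIntegrator().transform(prepared)

    def test_transform_matches_fitted_embedding(
        self, fitted_integrator, prepared
    ):
        np.testing.assert_array_equal(
            fitted_integrator.transform(prepared), fitted_integrator.z_hvg_
        )
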