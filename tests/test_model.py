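"""Model tests: architecture shape laws, gradient-path equivalence of the
entity-deduplicated batch path, training smoke/determinism, and overfit
capacity on a fixed small batch."""

import numpy as np
import pytest

from kmersig.dataset_io import make_plan
from kmersig.model import (
    ArchitectureSpec,
    TrainingConfig,
    build_model,
    cross_validate,
    prepare_tensors,
    train_fold,
)
from kmersig.synthetic import SyntheticSpec, generate


class TestArchitectureSpec:
    def test_default_flatten_widths(self):
        spec = ArchitectureSpec()
        assert spec.branch_flat_width(36) == 128  # 36->34->17->15->7->5->2
        assert spec.branch_flat_width(97) == 3200  # 97->95->47->45->22->20->10
        assert spec.concat_width == 3328

    def test_strict_mode_rejects_other_widths(self):
        bad = ArchitectureSpec(filters=(16, 16, 16), strict_concat=True)
        with pytest.raises(ValueError, match="1664"):
            bad.validate()

    def test_free_mode_builds_any_valid_spec(self):
        model = build_model(ArchitectureSpec(filters=(8, 8, 8)), seed=0)
        out = model.forward(
            np.zeros((2, 36, 36, 1), np.float32), np.zeros((2, 97, 97, 1), np.float32)
        )
        assert out.shape == (2,) and np.all(np.isfinite(out))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ArchitectureSpec(mol_shape=(8, 8)).branch_flat_width(8)


class TestForwardPaths:
    def test_built_model_concat_width_matches_spec(self):
        model = build_model(seed=1)
        assert model.concat_width == 3328

    def test_indexed_forward_equals_plain_forward(self, rng):
        """The per-unique-entity path must reproduce the naive expanded
        batch exactly (same branch outputs gathered per pair)."""
        model = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=3)
        mols = rng.random((5, 36, 36, 1)).astype(np.float32)
        prots = rng.random((3, 97, 97, 1)).astype(np.float32)
        d_idx = np.array([0, 1, 1, 4, 2, 0, 3])
        t_idx = np.array([2, 0, 2, 1, 1, 0, 2])
        plain = model.forward(mols[d_idx], prots[t_idx], train=False)
        ud, mi = np.unique(d_idx, return_inverse=True)
        ut, pi = np.unique(t_idx, return_inverse=True)
        indexed = model.forward_indexed(mols[ud], prots[ut], mi, pi, train=False)
        np.testing.assert_allclose(indexed, plain, rtol=1e-5, atol=1e-6)

    def test_indexed_backward_matches_expanded_gradients(self, rng):
        """Scatter-added entity gradients equal the sum of per-pair
        gradients from the expanded batch."""
        spec = ArchitectureSpec(filters=(2, 2, 2), dropout_rate=0.0)
        d_idx = np.array([0, 1, 0, 1, 0])
        t_idx = np.array([0, 0, 1, 1, 0])
        mols = rng.random((2, 36, 36, 1)).astype(np.float32)
        prots = rng.random((2, 97, 97, 1)).astype(np.float32)
        grad = rng.random(5).astype(np.float32)

        m1 = build_model(spec, seed=5)
        m1.forward(mols[d_idx], prots[t_idx], train=True)
        m1.backward(grad)
        expanded = [g.copy() for g in m1.grads()]

        m2 = build_model(spec, seed=5)
        ud, mi = np.unique(d_idx, return_inverse=True)
        ut, pi = np.unique(t_idx, return_inverse=True)
        m2.forward_indexed(mols[ud], prots[ut], mi, pi, train=True)
        m2.backward_indexed(grad)
        for ge, gi in zip(expanded, m2.grads()):
            np.testing.assert_allclose(gi, ge, rtol=1e-4, atol=1e-6)


@pytest.fixture(scope="module")
def small_training(small_dataset, small_plan):
    table, _, _ = small_dataset
    return prepare_tensors(table), small_plan


class TestTrainFold:
    def test_one_epoch_smoke(self, small_training):
        tensors, plan = small_training
        model = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=0)
        result = train_fold(model, tensors, plan, 0, TrainingConfig(epochs=1, seed=0))
        assert len(result.history) == 1
        assert np.isfinite(result.history["train_loss"]).all()
        assert np.isfinite(result.predictions).all()
        assert result.test_metrics["mse"] >= 0

    def test_checkpoint_round_trip(self, small_training, tmp_path):
        tensors, plan = small_training
        model = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=0)
        ckpt = tmp_path / "w.npz"
        result = train_fold(
            model, tensors, plan, 0, TrainingConfig(epochs=1, seed=0),
            checkpoint_path=str(ckpt),
        )
        fresh = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=99)
        fresh.load_weights(str(ckpt))
        for a, b in zip(fresh.params(), result.model.params()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_reproduces_weights_exactly(self, small_training):
        tensors, plan = small_training
        runs = []
        for _ in range(2):
            model = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=11)
            train_fold(model, tensors, plan, 1, TrainingConfig(epochs=2, seed=11))
            runs.append(model.get_weights())
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_invalid_fold_rejected(self, small_training):
        tensors, plan = small_training
        model = build_model(ArchitectureSpec(filters=(4, 4, 4)), seed=0)
        with pytest.raises(ValueError):
            train_fold(model, tensors, plan, 7, TrainingConfig(epochs=1, seed=0))

    def test_overfits_fixed_small_batch(self):
        """Capacity check: driven long enough on 64 fixed pairs the network
        memorizes them (training MSE < 0.01)."""
        table, _ = generate(SyntheticSpec(
            n_drugs=16, n_targets=4, density=1.0, seed=13, noise_sd=0.0,
            mol_len_mean=30, mol_len_range=(20, 60),
            prot_len_mean=230, prot_len_range=(215, 300)))
        tensors = prepare_tensors(table)
        model = build_model(ArchitectureSpec(dropout_rate=0.0), seed=13)
        model.head.layers[-1].b[...] = np.float32(tensors.affinity.mean())
        from kmersig import nn

        opt = nn.Adam(model.params(), model.grads(), eps=1e-7)
        ud, mi = np.unique(tensors.drug_idx, return_inverse=True)
        ut, pi = np.unique(tensors.target_idx, return_inverse=True)
        xm, xp = tensors.mol_images[ud], tensors.prot_images[ut]
        y = tensors.affinity
        final = np.inf
        for _ in range(200):
            pred = model.forward_indexed(xm, xp, mi, pi, train=True)
            resid = pred - y
            final = float(np.mean(resid**2))
            if final < 0.01:
                break
            model.backward_indexed((2.0 / y.size * resid).astype(np.float32))
            opt.step()
        assert final < 0.01


class TestCrossValidate:
    def test_report_shape_and_summary(self, small_dataset, small_plan):
        table, _, _ = small_dataset
        report = cross_validate(
            table, small_plan,
            ArchitectureSpec(filters=(4, 4, 4)),
            TrainingConfig(epochs=1, seed=0),
        )
        assert list(report.index) == ["0", "1", "2", "3", "4", "mean", "std"]
        assert {"mse", "ci", "rm2", "aupr", "acc"} <= set(report.columns)
        folds = report.loc[[str(i) for i in range(5)]]
        assert np.allclose(report.loc["mean", "mse"], folds["mse"].mean())

    def test_constant_affinity_flagged(self, small_dataset, small_plan):
        table, _, _ = small_dataset
        const = type(table)(
            drugs=table.drugs, targets=table.targets,
            affinity=np.where(np.isfinite(table.affinity), 5.0, np.nan),
            kind=table.kind,
        )
        report = cross_validate(
            const, small_plan,
            ArchitectureSpec(filters=(2, 2, 2)),
            TrainingConfig(epochs=1, seed=0),
        )
        assert report.loc["0"].isna().any()  # CI/rm2 undefined, surfaced as NaN
        assert np.isfinite(report.loc["0", "mse"])
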