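"""Model construction, PCA branch, gradient correctness, and training contracts."""

import numpy as np
import pytest

from mulcnn import ops
from mulcnn.errors import ConfigurationError, ValidationError
from mulcnn.model import (
    ConvBranchConfig,
    ModelConfig,
    TrainedModel,
    build_model,
    fine_tune,
    pca_fit,
    pca_transform,
    train,
)

TINY_CONFIG = dict(
    conv_branches=[
        ConvBranchConfig(filters=4, kernel=(2, 2), pools=[(2, 2)], dropout=0.0),
        ConvBranchConfig(filters=3, kernel=(3, 3), pools=[(2, 2)], dropout=0.0),
    ],
    pca_components=4,
    hidden_sizes=(8, 8, 4),
)


def _tiny_model(seed=0, dtype=np.float64, **overrides):
    cfg = ModelConfig(seed=seed, **{**TINY_CONFIG, **overrides})
    return build_model(cfg, n_genes=36, n_classes=3, dtype=dtype)


class TestPCA:
    def test_line_explains_all_variance(self):
        t = np.linspace(-1, 1, 20)
        X = np.stack([t, 2 * t], axis=1)
        model = pca_fit(X, 1)
        total = X.var(axis=0, ddof=1).sum()
        assert model.explained_variance[0] == pytest.approx(total)

    def test_mean_maps_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 6))
        model = pca_fit(X, 3)
        np.testing.assert_allclose(
            pca_transform(model, X.mean(axis=0, keepdims=True)),
            np.zeros((1, 3)),
            atol=1e-10,
        )

    def test_components_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 10))
        model = pca_fit(X, 3)
        cov = np.cov(X, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        top = eigvec[:, ::-1][:, :3].T
        for comp, ref in zip(model.components, top):
            sign = np.sign(comp @ ref)
            np.testing.assert_allclose(comp, sign * ref, atol=1e-8)
        np.testing.assert_allclose(
            model.explained_variance, eigval[::-1][:3], atol=1e-8
        )

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        model = pca_fit(rng.standard_normal((30, 8)), 5)
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(5), atol=1e-10
        )

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            pca_fit(np.ones((5, 3)), 5)


class TestBuildModel:
    def test_default_architecture_widths(self):
        model = build_model(ModelConfig(seed=0), n_genes=1024, n_classes=5)
        # 32x32 image: branch A 256 x 7x7, branch B 128 x 9x9, plus 50 PCs
        assert model.feature_width() == 256 * 7 * 7 + 128 * 9 * 9 + 50
        assert model.mlp_weights[0].shape == (model.feature_width(), 128)
        assert [w.shape[1] for w in model.mlp_weights] == [128, 128, 64, 5]

    def test_no_conv_ablation_width(self):
        model = build_model(
            ModelConfig(seed=0, enable_conv=False), n_genes=1024, n_classes=5
        )
        assert model.mlp_weights[0].shape[0] == 50

    def test_no_pca_ablation_width(self):
        model = build_model(
            ModelConfig(seed=0, enable_pca=False), n_genes=1024, n_classes=5
        )
        assert model.mlp_weights[0].shape[0] == 256 * 7 * 7 + 128 * 9 * 9

    def test_both_branches_disabled_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(enable_conv=False, enable_pca=False)

    def test_same_seed_identical_weights(self):
        a = _tiny_model(seed=5)
        b = _tiny_model(seed=5)
        for wa, wb in zip(a.mlp_weights, b.mlp_weights):
            np.testing.assert_array_equal(wa, wb)
        for pa, pb in zip(a.conv_params, b.conv_params):
            np.testing.assert_array_equal(pa["kernels"], pb["kernels"])

    def test_image_too_small_reports_shapes(self):
        cfg = ModelConfig(
            seed=0,
            conv_branches=[
                ConvBranchConfig(filters=2, kernel=(2, 2), pools=[(3, 3), (3, 3)])
            ],
            pca_components=2,
        )
        with pytest.raises(ConfigurationError, match="pool"):
            build_model(cfg, n_genes=16, n_classes=2)

    def test_config_roundtrips_through_dict(self):
        cfg = ModelConfig(seed=9, learning_rate=2e-3)
        back = ModelConfig.from_dict(cfg.to_dict())
        assert back.to_dict() == cfg.to_dict()


class TestGradients:
    """Backprop against central finite differences on a tiny float64 network."""

    def _loss(self, model, images, pca_feats, Y):
        probs, _ = model._forward(images, pca_feats, training=False)
        return ops.categorical_cross_entropy(Y, probs, eps=1e-300)

    def test_backprop_matches_finite_differences(self):
        model = _tiny_model(seed=3)
        rng = np.random.default_rng(4)
        n = 6
        values = np.abs(rng.standard_normal((n, 36)))
        model.pca_model = pca_fit(values, 4)
        images, pca_feats = model.features_for(values)
        Y = np.eye(3)[rng.integers(0, 3, size=n)].astype(np.float64)

        probs, cache = model._forward(
            images, pca_feats, training=True, rng=np.random.default_rng(0)
        )
        grads = model._backward(probs, Y, cache)

        eps = 1e-6
        checked = 0
        arrays = (
            [(p["kernels"], g["kernels"]) for p, g in zip(model.conv_params, grads["conv"])]
            + [(p["bias"], g["bias"]) for p, g in zip(model.conv_params, grads["conv"])]
            + list(zip(model.mlp_weights, grads["mlp_W"]))
            + list(zip(model.mlp_biases, grads["mlp_b"]))
        )
        param_rng = np.random.default_rng(9)
        for arr, grad in arrays:
            flat = arr.ravel()
            gflat = grad.ravel()
            for idx in param_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = self._loss(model, images, pca_feats, Y)
                flat[idx] = orig - eps
                down = self._loss(model, images, pca_feats, Y)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                denom = max(abs(numeric), abs(gflat[idx]), 1e-8)
                assert abs(numeric - gflat[idx]) / denom < 1e-4
                checked += 1
        assert checked >= 40


class TestTraining:
    def _separable_data(self, n_per=40, n_genes=36, seed=0):
        rng = np.random.default_rng(seed)
        a = np.abs(rng.standard_normal((n_per, n_genes)))
        b = np.abs(rng.standard_normal((n_per, n_genes)))
        a[:, :6] += 5.0
        b[:, 6:12] += 5.0
        X = np.vstack([a, b])
        y = ["A"] * n_per + ["B"] * n_per
        return X, y

    def test_loss_descends_on_separable_classes(self):
        X, y = self._separable_data()
        model = build_model(
            ModelConfig(seed=0, **{**TINY_CONFIG, "learning_rate": 1e-2}),
            gene_ids=[f"g{i}" for i in range(36)],
            class_names=["A", "B"],
        )
        _, history = train(model, (X, y), epochs=50)
        assert history.train_loss[-1] < history.train_loss[0]

    def test_same_seed_identical_history(self):
        X, y = self._separable_data()
        runs = []
        for _ in range(2):
            model = build_model(
                ModelConfig(seed=11, **TINY_CONFIG),
                gene_ids=[f"g{i}" for i in range(36)],
                class_names=["A", "B"],
            )
            _, h = train(model, (X, y), (X, y), epochs=5)
            runs.append(h)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_zero_learning_rate_freezes_weights(self):
        X, y = self._separable_data()
        model = build_model(
            ModelConfig(seed=2, **{**TINY_CONFIG, "learning_rate": 0.0}),
            gene_ids=[f"g{i}" for i in range(36)],
            class_names=["A", "B"],
        )
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        train(model, (X, y), epochs=3)
        after = model.state_arrays()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_single_class_rejected(self):
        X, _ = self._separable_data()
        model = _tiny_model(seed=0)
        with pytest.raises(ValidationError):
            train(model, (X, ["A"] * X.shape[0]), epochs=1)

    def test_inference_deterministic(self):
        X, y = self._separable_data()
        model = build_model(
            ModelConfig(seed=1, **TINY_CONFIG),
            gene_ids=[f"g{i}" for i in range(36)],
            class_names=["A", "B"],
        )
        fitted, _ = train(model, (X, y), epochs=2)
        p1 = fitted.predict_proba_values(X)
        p2 = fitted.predict_proba_values(X)
        np.testing.assert_array_equal(p1, p2)


class TestFineTune:
    def _pretrained(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.standard_normal((60, 36)))
        X[:30, :6] += 4
        X[30:, 6:12] += 4
        y = ["A"] * 30 + ["B"] * 30
        model = build_model(
            ModelConfig(seed=0, **TINY_CONFIG),
            gene_ids=[f"g{i}" for i in range(36)],
            class_names=["A", "B"],
        )
        fitted, _ = train(model, (X, y), epochs=3)
        return fitted, X, y

    def test_zero_epochs_same_classes_is_identity(self):
        model, X, y = self._pretrained()
        tuned, _ = fine_tune(model, (X, y), epochs=0, class_names=["A", "B"])
        np.testing.assert_array_equal(
            model.predict_proba_values(X), tuned.predict_proba_values(X)
        )

    def test_new_class_set_resizes_output(self):
        model, X, y = self._pretrained()
        y3 = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        tuned, _ = fine_tune(model, (X, y3), epochs=1)
        assert tuned.class_names == ["A", "B", "C"]
        assert tuned.mlp_weights[-1].shape[1] == 3
        # hidden layers are warm-started, not re-initialized
        np.testing.assert_array_equal(tuned.mlp_weights[0].shape, model.mlp_weights[0].shape)

    def test_empty_target_rejected(self):
        model, X, y = self._pretrained()
        with pytest.raises(ValidationError):
            fine_tune(model, (X[:0], []), epochs=1)

    def test_transfer_improves_over_unadapted_model(self):
        """Source/target share marker structure but differ by a batch effect;
        fine-tuning on a small target subset should beat direct transfer."""
        from mulcnn.preprocess import normalize_cpm_log
        from mulcnn.synthetic import SimConfig, generate_batch_pair

        cfg = SimConfig(
            n_genes=144,
            cell_type_sizes={f"t{i}": 120 for i in range(3)},
            markers_per_type=8,
            marker_fold=4.0,
            dropout_rate=0.2,
            seed=5,
        )
        (X1, y1), (X2, y2), _ = generate_batch_pair(cfg, batch_shift=1.5)
        N1 = normalize_cpm_log(X1)
        N2 = normalize_cpm_log(X2)
        model = build_model(
            ModelConfig(
                seed=5,
                conv_branches=[
                    ConvBranchConfig(filters=8, kernel=(2, 2), pools=[(2, 2)], dropout=0.25)
                ],
                pca_components=10,
                hidden_sizes=(16, 16, 8),
                learning_rate=1e-2,
            ),
            gene_ids=N1.gene_ids,
            class_names=sorted(set(y1.labels)),
        )
        source, _ = train(model, (N1.values, y1.labels), epochs=60)

        rng = np.random.default_rng(0)
        subset = rng.choice(N2.n_cells, size=N2.n_cells // 10, replace=False)
        rest = np.setdiff1d(np.arange(N2.n_cells), subset)
        tuned, _ = fine_tune(
            source,
            (N2.values[subset], [y2.labels[i] for i in subset]),
            epochs=100,
            class_names=source.class_names,
        )
        truth = np.asarray(y2.labels)[rest]

        def acc(m):
            probs = m.predict_proba_values(N2.values[rest])
            return np.mean(np.array(m.class_names)[probs.argmax(1)] == truth)

        assert acc(tuned) > acc(source)
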