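"""Architecture assembly, determinism and parameter accounting."""

import numpy as np
import pytest

from csatdta.attention import count_params_delta
from csatdta.model import (
    BranchConfig,
    ModelConfig,
    build_model,
    predict,
)


def tiny_config(**kw):
    base = dict(
        drug_branch=BranchConfig(
            vocab_size=64, max_len=24, kernel_size=4, n_heads=2,
            head_depth=2, embed_dim=12, base_filters=8,
        ),
        protein_branch=BranchConfig(
            vocab_size=25, max_len=40, kernel_size=6, n_heads=2,
            head_depth=2, embed_dim=12, base_filters=8,
        ),
        dense_sizes=(32, 32, 16),
        seed=9,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(tiny_config())


@pytest.fixture(scope="module")
def tiny_batch():
    r = np.random.default_rng(4)
    return (r.integers(0, 65, size=(6, 24)), r.integers(0, 26, size=(6, 40)))


class TestConfig:
    def test_default_drug_attention_matches_table(self):
        spec = ModelConfig().drug_branch.attention_spec()
        assert spec.n_heads == 4 and spec.d_k == spec.d_v == 8

    def test_default_protein_attention_matches_table(self):
        spec = ModelConfig().protein_branch.attention_spec()
        assert spec.n_heads == 10 and spec.d_k == spec.d_v == 50

    def test_default_head_and_training_settings(self):
        cfg = ModelConfig()
        assert cfg.dense_sizes == (1024, 1024, 512)
        assert cfg.dropout_rate == 0.1
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 64
        assert cfg.optimizer_name == "adadelta"
        assert cfg.initializer_name == "glorot_normal"

    def test_invalid_configs_rejected_before_allocation(self):
        with pytest.raises(ValueError, match="conv filter"):
            BranchConfig(vocab_size=64, max_len=24, kernel_size=4,
                         n_heads=2, head_depth=12, base_filters=8).validate()
        with pytest.raises(ValueError, match="optimizer"):
            tiny_config(optimizer_name="rmsprop").validate()
        with pytest.raises(ValueError, match="even"):
            BranchConfig(vocab_size=25, max_len=41, kernel_size=6,
                         n_heads=2, head_depth=2, base_filters=8,
                         downsample_attention=True).validate()

    def test_dict_round_trip(self):
        cfg = tiny_config()
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_branch_outputs_are_3f_and_head_input_6f(self, tiny_model, tiny_batch):
        d, p = tiny_batch
        pooled_d = tiny_model.drug(d, training=False, bn_training=False)
        pooled_p = tiny_model.protein(p, training=False, bn_training=False)
        assert pooled_d.shape == (6, 24)  # 3F with F=8
        assert pooled_p.shape == (6, 24)
        assert tiny_model.dense[0][0].shape[0] == 48  # 6F head input

    def test_prediction_is_finite_scalar_per_pair(self, tiny_model, tiny_batch):
        out = tiny_model.predict_batch(*tiny_batch)
        assert out.shape == (6,) and np.isfinite(out).all()

    def test_inference_is_bit_identical(self, tiny_model, tiny_batch):
        a = tiny_model.predict_batch(*tiny_batch)
        b = tiny_model.predict_batch(*tiny_batch)
        np.testing.assert_array_equal(a, b)

    def test_batch_prediction_equals_single_pair_calls(self, tiny_model, tiny_batch):
        d, p = tiny_batch
        batch = tiny_model.predict_batch(d, p)
        singles = [
            tiny_model.predict_batch(d[i : i + 1], p[i : i + 1])[0]
            for i in range(len(d))
        ]
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_predict_single_pair_helper(self, tiny_model):
        from csatdta.encoding import encode_protein, encode_smiles

        score = predict(
            tiny_model,
            encode_smiles("CCO", max_len=24),
            encode_protein("MKTAYIAK", max_len=40),
        )
        assert np.isfinite(score)

    def test_token_validation(self, tiny_model):
        with pytest.raises(ValueError, match="shape"):
            tiny_model.predict_batch(np.zeros((2, 10), int), np.zeros((2, 40), int))
        with pytest.raises(ValueError, match="codes"):
            tiny_model.predict_batch(
                np.full((1, 24), 99), np.zeros((1, 40), int)
            )

    def test_dropout_off_makes_train_and_eval_agree(self, tiny_batch):
        model = build_model(tiny_config(dropout_rate=0.0))
        d, p = tiny_batch
        train_out = model.forward(d, p, training=True, bn_training=False)
        eval_out = model.forward(d, p, training=False)
        np.testing.assert_allclose(train_out.data, eval_out.data, atol=1e-5)


class TestDeterminism:
    def test_same_seed_same_weights(self):
        a, b = build_model(tiny_config()), build_model(tiny_config())
        for (ka, va), (kb, vb) in zip(
            a.parameters().items(), b.parameters().items()
        ):
            assert ka == kb
            np.testing.assert_array_equal(va.data, vb.data)

    def test_different_seed_different_weights(self):
        a = build_model(tiny_config())
        b = build_model(tiny_config(seed=10))
        diffs = [
            not np.array_equal(va.data, vb.data)
            for va, vb in zip(a.parameters().values(), b.parameters().values())
        ]
        assert any(diffs)


class TestParameterAccounting:
    @pytest.mark.parametrize("branch_name", ["drug", "protein"])
    def test_augmented_layer_delta_matches_closed_form(self, branch_name):
        """Weights of the terminal AA-conv layer, minus a plain 3F conv,
        equal the accounting formula for 1-D kernels (biases and relative
        embeddings excluded)."""
        model = build_model(tiny_config())
        branch = getattr(model, branch_name)
        spec = branch.cfg.attention_spec()
        attn_weights = (
            sum(w.data.size for w in branch.mha.w_q)
            + sum(w.data.size for w in branch.mha.w_k)
            + sum(w.data.size for w in branch.mha.w_v)
            + branch.mha.w_o.data.size
        )
        augmented = branch.aa_kernel.data.size + attn_weights
        plain = branch.cfg.kernel_size * spec.f_in * spec.f_out
        assert augmented - plain == count_params_delta(
            spec, spatial_dims=1
        ).delta

    def test_gradient_reaches_every_layer(self, tiny_batch):
        from csatdta._autodiff import Tensor
        from csatdta.training import _make_optimizer

        model = build_model(tiny_config())
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        d, p = tiny_batch
        pred = model.forward(d, p, training=True)
        loss = ((pred - Tensor(np.linspace(5, 9, 6))) ** 2.0).mean()
        opt = _make_optimizer("adam", model.parameters(), 1e-2)
        loss.backward()
        opt.step()
        layers_changed = {}
        for k, v in model.parameters().items():
            layer = k.rsplit(".", 1)[0]
            layers_changed.setdefault(layer, False)
            if not np.array_equal(before[k], v.data):
                layers_changed[layer] = True
        dead = [k for k, changed in layers_changed.items() if not changed]
        assert not dead, f"no weight moved in layers: {dead}"


class TestStatePersistence:
    def test_state_dict_round_trip_preserves_predictions(self, tiny_batch):
        m1 = build_model(tiny_config())
        state = m1.state_dict()
        m2 = build_model(tiny_config(seed=99))
        m2.load_state_dict(state)
        d, p = tiny_batch
        np.testing.assert_array_equal(
            m1.predict_batch(d, p), m2.predict_batch(d, p)
        )

    def test_missing_parameter_rejected(self):
        m = build_model(tiny_config())
        state = m.state_dict()
        state.pop("head.out.w")
        with pytest.raises(KeyError):
            build_model(tiny_config()).load_state_dict(state)
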