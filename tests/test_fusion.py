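"""Architecture contracts and the cross-sequence attention oracle."""

import numpy as np
import pytest

from bpfuse.encoder import EncoderSpec
from bpfuse.fusion import (
    AttentionSpec,
    CrossAttentionModel,
    CrossSequenceAttention,
    FusionModelSpec,
    MultiEncoderModel,
    ThreeChannelModel,
    build_model,
)
from bpfuse.nn import Tensor, bce_with_logits

from _oracles import attention_oracle


def desk_spec(family, use_clinical=False, d=8, **kw):
    in_channels = 3 if family == "3ch" else 1
    enc = EncoderSpec(stage_widths=(d // 2, d), blocks_per_stage=(1, 1), dropout=0.0,
                      in_channels=in_channels)
    attention = AttentionSpec(d=d, H=2) if family == "meca" else None
    return FusionModelSpec(family=family, encoder=enc, use_clinical=use_clinical,
                           attention=attention, **kw)


def batch(B=2, shape=(4, 8, 8), seed=0):
    return np.random.default_rng(seed).normal(size=(B, 3) + shape).astype(np.float32)


class TestAttentionSpec:
    def test_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionSpec(d=6, H=4)

    def test_dh(self):
        assert AttentionSpec(d=512, H=2).d_h == 256


class TestCrossSequenceAttention:
    def _module(self, d, H, seed=0, **kw):
        att = CrossSequenceAttention(AttentionSpec(d=d, H=H, **kw),
                                     rng=np.random.default_rng(seed))
        att.eval()
        return att

    def _set_weights(self, att, wq, wk, wv):
        for i in range(3):
            att.w_q[i].data = np.asarray(wq[i], dtype=np.float32)
            att.w_k[i].data = np.asarray(wk[i], dtype=np.float32)
            att.w_v[i].data = np.asarray(wv[i], dtype=np.float32)

    def test_uniform_probs_for_identical_inputs_and_shared_weights(self):
        d, H = 4, 2
        att = self._module(d, H)
        w = np.random.default_rng(1).normal(size=(d, d))
        self._set_weights(att, [w] * 3, [w] * 3, [w] * 3)
        h = Tensor(np.tile(np.array([[1.0, 2.0, -1.0, 0.5]], dtype=np.float32), (2, 1)))
        att([h, h, h])
        np.testing.assert_allclose(att.last_attn_probs, 1.0 / 3.0, atol=1e-6)

    def test_probs_sum_to_one_always(self):
        rng = np.random.default_rng(2)
        att = self._module(8, 2)
        hs = [Tensor(rng.normal(size=(5, 8)).astype(np.float32)) for _ in range(3)]
        att(hs)
        np.testing.assert_allclose(att.last_attn_probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_small_integer_instance_matches_oracle(self):
        d, H = 4, 2
        rng = np.random.default_rng(3)
        wq = [rng.integers(-2, 3, size=(d, d)).astype(float) for _ in range(3)]
        wk = [rng.integers(-2, 3, size=(d, d)).astype(float) for _ in range(3)]
        wv = [rng.integers(-2, 3, size=(d, d)).astype(float) for _ in range(3)]
        hs_np = [rng.integers(-2, 3, size=d).astype(float) for _ in range(3)]
        att = self._module(d, H)
        self._set_weights(att, wq, wk, wv)
        # float32 weights but exact small integers: tight tolerance is fair
        out = att([Tensor(h[None, :].astype(np.float32)) for h in hs_np])
        expected, probs = attention_oracle(hs_np, wq, wk, wv, H)
        for o, e in zip(out, expected):
            np.testing.assert_allclose(o.data[0], e, atol=1e-5)
        np.testing.assert_allclose(att.last_attn_probs[:, 0], probs, atol=1e-6)

    @pytest.mark.parametrize("d,H", [(2, 1), (4, 2), (8, 2), (8, 1)])
    @pytest.mark.parametrize("cascade", [True, False])
    def test_matches_oracle_random_instances(self, d, H, cascade):
        rng = np.random.default_rng(d * 10 + H + cascade)
        for rep in range(10):
            wq = [rng.normal(size=(d, d)) for _ in range(3)]
            wk = [rng.normal(size=(d, d)) for _ in range(3)]
            wv = [rng.normal(size=(d, d)) for _ in range(3)]
            hs_np = [rng.normal(size=d) for _ in range(3)]
            att = CrossSequenceAttention(AttentionSpec(d=d, H=H, cascade=cascade))
            for i in range(3):  # float64 weights for exact comparison
                att.w_q[i] = type(att.w_q[i])(wq[i], dtype=np.float64)
                att.w_k[i] = type(att.w_k[i])(wk[i], dtype=np.float64)
                att.w_v[i] = type(att.w_v[i])(wv[i], dtype=np.float64)
            out = att([Tensor(h[None, :]) for h in hs_np])
            expected, _ = attention_oracle(hs_np, wq, wk, wv, H, cascade=cascade)
            for o, e in zip(out, expected):
                np.testing.assert_allclose(o.data[0], e, atol=1e-6)

    def test_key_scaling_scales_scores(self):
        # doubling all keys doubles the pre-softmax scores; with H=d (d_h=1)
        # the score reduces to a plain dot product / 1
        d = 4
        att = self._module(d, 1)
        rng = np.random.default_rng(5)
        wq = [rng.normal(size=(d, d)) for _ in range(3)]
        wk = [rng.normal(size=(d, d)) for _ in range(3)]
        wv = [rng.normal(size=(d, d)) for _ in range(3)]
        hs_np = [rng.normal(size=d) for _ in range(3)]
        _, probs1 = attention_oracle(hs_np, wq, wk, wv, 1)
        # recompute raw scores by hand for scaled keys
        q = hs_np[0] @ wq[0]
        for c in (1.0, 2.0, 5.0):
            k = [hs_np[j] @ (c * wk[j]) for j in range(3)]
            scores = [float(q @ kj) / np.sqrt(d) for kj in k]
            base = [float(q @ (hs_np[j] @ wk[j])) / np.sqrt(d) for j in range(3)]
            np.testing.assert_allclose(scores, [c * b for b in base], rtol=1e-9)

    def test_dh_one_reduces_to_plain_dot(self):
        d = 4  # H = 4 -> d_h = 1, sqrt(d_h) = 1
        rng = np.random.default_rng(6)
        wq = [rng.normal(size=(d, d)) for _ in range(3)]
        wk = [rng.normal(size=(d, d)) for _ in range(3)]
        wv = [rng.normal(size=(d, d)) for _ in range(3)]
        hs_np = [rng.normal(size=d) for _ in range(3)]
        _, probs = attention_oracle(hs_np, wq, wk, wv, H=4, cascade=False)
        q = [hs_np[i] @ wq[i] for i in range(3)]
        k = [hs_np[j] @ wk[j] for j in range(3)]
        for head in range(4):
            raw = [q[0][head] * k[j][head] for j in range(3)]
            e = np.exp(raw - np.max(raw))
            np.testing.assert_allclose(probs[head][0], e / e.sum(), atol=1e-9)

    def test_nonfinite_inputs_rejected(self):
        att = self._module(4, 2)
        bad = np.zeros((1, 4), dtype=np.float32)
        bad[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            att([Tensor(bad), Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4)))])


class TestArchitectures:
    def test_3ch_fused_lengths(self):
        spec = desk_spec("3ch", use_clinical=True)
        model = build_model(spec, seed=0)
        model.eval()
        model.forward(batch(), np.zeros((2, 3)))
        assert model.last_fused_dim == spec.encoder.feature_dim + 3
        spec2 = desk_spec("3ch", use_clinical=False)
        model2 = build_model(spec2, seed=0)
        model2.eval()
        model2.forward(batch())
        assert model2.last_fused_dim == spec2.encoder.feature_dim

    def test_default_fused_dim_is_1539(self):
        spec = FusionModelSpec(family="me", encoder=EncoderSpec(), use_clinical=True)
        assert spec.fused_dim == 1539

    def test_me_reduced_fused_dim(self):
        spec = desk_spec("me", use_clinical=False, d=16)
        model = build_model(spec, seed=0)
        model.eval()
        model.forward(batch())
        assert model.last_fused_dim == 48

    def test_probabilities_in_unit_interval(self):
        for family in ("3ch", "me", "meca"):
            model = build_model(desk_spec(family), seed=1)
            model.eval()
            probs = model.predict_proba(batch(B=4))
            assert probs.shape == (4,)
            assert np.all((probs > 0) & (probs < 1))

    def test_batch_permutation_equivariance(self):
        model = build_model(desk_spec("me"), seed=2)
        model.eval()
        x = batch(B=4, seed=9)
        probs = model.predict_proba(x)
        perm = [2, 0, 3, 1]
        probs_perm = model.predict_proba(x[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], rtol=1e-5)

    def test_single_modality_subset(self):
        spec = desk_spec("3ch", sequence_subset=(1,))
        model = build_model(spec, seed=0)
        model.eval()
        x = batch(B=3, seed=4)
        probs = model.predict_proba(x)
        # altering unused channels must not change the output
        x2 = x.copy()
        x2[:, 0] += 100.0
        x2[:, 2] -= 50.0
        np.testing.assert_allclose(model.predict_proba(x2), probs, rtol=1e-6)

    def test_missing_clinical_errors(self):
        model = build_model(desk_spec("me", use_clinical=True), seed=0)
        model.eval()
        with pytest.raises(ValueError, match="clinical"):
            model.forward(batch())

    def test_degenerate_attention_equals_me(self):
        """Zero attention projections + ADD residual reduce MECA to ME."""
        me_spec = desk_spec("me")
        meca_spec = desk_spec("meca")
        me = build_model(me_spec, seed=7)
        meca = build_model(meca_spec, seed=7)
        # align encoder + classifier weights
        me_state = me.state_dict()
        meca.load_state_dict({**meca.state_dict(), **me_state})
        for i in range(3):
            meca.attention.w_v[i].data = np.zeros_like(meca.attention.w_v[i].data)
        me.eval(), meca.eval()
        x = batch(B=3, seed=11)
        np.testing.assert_allclose(
            meca.predict_proba(x), me.predict_proba(x), atol=1e-7
        )

    def test_gradient_reaches_all_attention_projections(self):
        model = build_model(desk_spec("meca"), seed=3)
        model.train()
        x = batch(B=4, seed=5)
        logits = model.forward(x)
        loss = bce_with_logits(logits, np.array([0, 1, 1, 0]))
        loss.backward()
        for ws in (model.attention.w_q, model.attention.w_k, model.attention.w_v):
            for w in ws:
                assert w.grad is not None
                assert np.abs(w.grad).sum() > 0

    def test_shared_encoder_flag(self):
        spec = desk_spec("me", share_encoders=True)
        model = build_model(spec, seed=0)
        assert model.encoders[0] is model.encoders[1] is model.encoders[2]
        n_shared = len(model.parameters())
        n_sep = len(build_model(desk_spec("me"), seed=0).parameters())
        assert n_shared < n_sep
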