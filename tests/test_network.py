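"""Architecture contracts: shapes, PPM/AG behaviour, wiring, checkpoints."""

import numpy as np
import pytest

from echoseg import nn
from echoseg.network import (
    MICRO_WIDTHS,
    AttentionGate,
    ModelConfig,
    PyramidPooling,
    build_model,
    forward_logits,
    forward_predict,
    load_checkpoint,
    save_checkpoint,
)
from echoseg.nn import Tensor


def test_ppm_doubles_channels_preserves_spatial(rng):
    ppm = PyramidPooling(512, (1, 2, 3, 6), rng)
    x = Tensor(rng.normal(size=(1, 16, 16, 512)).astype(np.float32))
    out = ppm(x)
    assert out.data.shape == (1, 16, 16, 1024)  # 512 + 4·128


def test_ppm_constant_input_pools_to_constant(rng):
    ppm = PyramidPooling(8, (1, 2, 3), rng)
    x = Tensor(np.full((1, 12, 12, 8), 0.7, dtype=np.float32))
    # every pooled branch of a constant input is that constant before conv
    for b in ppm.bins:
        pooled = nn.adaptive_avg_pool(x, (b, b))
        assert np.allclose(pooled.data, 0.7, atol=1e-6)


def test_ppm_bin_larger_than_input_raises(rng):
    ppm = PyramidPooling(8, (1, 2, 3, 6), rng)
    x = Tensor(rng.normal(size=(1, 4, 4, 8)))
    with pytest.raises(ValueError):
        ppm(x)


def test_attention_gate_zero_weights_halve_features(rng):
    ag = AttentionGate(signal_ch=4, feat_ch=6, rng=rng)
    for p in ag.named_parameters().values():
        p.data[...] = 0.0
    ag.eval()
    sig = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
    feat = Tensor(rng.normal(size=(1, 8, 8, 6)).astype(np.float32))
    q = ag.coefficient(sig, feat)
    assert np.allclose(q.data, 0.5, atol=1e-6)
    out = ag(sig, feat)
    assert np.allclose(out.data, feat.data / 2, atol=1e-6)


def test_attention_coefficient_in_open_unit_interval(rng):
    ag = AttentionGate(signal_ch=3, feat_ch=5, rng=rng)
    sig = Tensor(rng.normal(size=(2, 4, 4, 3)))
    feat = Tensor(rng.normal(size=(2, 8, 8, 5)))
    q = ag.coefficient(sig, feat).data
    assert q.shape == (2, 8, 8, 1)
    assert (q > 0).all() and (q < 1).all()
    # multiplicative gating: zero features stay zero regardless of the signal
    out = ag(sig, Tensor(np.zeros((2, 8, 8, 5))))
    assert np.allclose(out.data, 0.0)


def test_ds_mode_emits_four_heads_of_input_size(micro_cfg, rng):
    model = build_model(micro_cfg, seed=0)
    heads = forward_logits(model, rng.random((2, 64, 64), dtype=np.float32))
    assert len(heads) == 4
    for h in heads:
        assert h.shape == (2, 6, 64, 64)


@pytest.mark.parametrize("mode,column", [("L2", 2), ("L3", 3), ("L4", 4)])
def test_single_depth_modes_emit_one_head(micro_cfg, mode, column, rng):
    import dataclasses

    cfg = dataclasses.replace(micro_cfg, decode_mode=mode)
    model = build_model(cfg, seed=0)
    heads = forward_logits(model, rng.random((1, 32, 32), dtype=np.float32))
    assert len(heads) == 1
    assert heads[0].shape == (1, 6, 32, 32)


def test_l_mode_heads_match_ds_columns(micro_cfg, rng):
    """The single L-mode output is the DS model's corresponding column head."""
    import dataclasses

    x = rng.random((1, 32, 32), dtype=np.float32)
    ds = build_model(micro_cfg, seed=3)
    ds.eval()
    ds_heads = forward_logits(ds, x)
    for mode, j in (("L2", 2), ("L3", 3), ("L4", 4)):
        m = build_model(dataclasses.replace(micro_cfg, decode_mode=mode), seed=0)
        m.load_state_dict(ds.state_dict())
        m.eval()
        (h,) = forward_logits(m, x)
        assert np.allclose(h, ds_heads[j - 1], atol=1e-6)


def test_parameter_count_strictly_increases_with_modules():
    base = dict(encoder_widths=MICRO_WIDTHS, ppm_bins=(1, 2))
    n_base = build_model(ModelConfig(**base, ppm_enabled=False, ag_enabled=False)).num_parameters()
    n_ppm = build_model(ModelConfig(**base, ppm_enabled=True, ag_enabled=False)).num_parameters()
    n_ag = build_model(ModelConfig(**base, ppm_enabled=False, ag_enabled=True)).num_parameters()
    n_both = build_model(ModelConfig(**base, ppm_enabled=True, ag_enabled=True)).num_parameters()
    assert n_base < n_ppm < n_both and n_base < n_ag < n_both


def test_dense_skip_input_channels():
    """Node X[i][j] consumes j same-depth skips plus the upsampled deeper node."""
    cfg = ModelConfig(encoder_widths=MICRO_WIDTHS, ppm_enabled=False, ag_enabled=False)
    model = build_model(cfg)
    w = cfg.encoder_widths
    for j in range(1, 5):
        for i in range(0, 5 - j):
            conv1 = getattr(model, f"node{i}_{j}").conv1.weight
            assert conv1.data.shape[1] == j * w[i] + w[i + 1]


def test_plain_nested_unet_weight_transplant(rng):
    """With PPM and AG disabled, the forward pass equals an independently
    wired plain U-Net++ using the same weights."""
    cfg = ModelConfig(
        encoder_widths=MICRO_WIDTHS, ppm_enabled=False, ag_enabled=False, decode_mode="DS"
    )
    model = build_model(cfg, seed=5)
    model.eval()
    state = model.state_dict()
    x = rng.random((1, 32, 32), dtype=np.float32)
    heads = forward_logits(model, x)

    # independent reference: plain numpy eval-mode forward from the state dict
    def conv(v, name, padding):
        w = state[f"{name}.weight"]
        t = nn.conv2d(Tensor(v), Tensor(w),
                      Tensor(state[f"{name}.bias"]) if f"{name}.bias" in state else None,
                      padding=padding)
        return t.data

    def bn(v, name):
        g, b = state[f"{name}.gamma"], state[f"{name}.beta"]
        rm, rv = state[f"{name}.running_mean"], state[f"{name}.running_var"]
        return g * (v - rm) / np.sqrt(rv + 1e-5) + b

    def block(v, name):
        v = np.maximum(bn(conv(v, f"{name}.conv1", 1), f"{name}.bn1"), 0)
        return np.maximum(bn(conv(v, f"{name}.conv2", 1), f"{name}.bn2"), 0)

    def pool(v):
        return nn.maxpool2x2(Tensor(v)).data

    def up(v, name, hw):
        return conv(nn.bilinear_resize(Tensor(v), hw).data, f"{name}.conv", 0)

    grid = {}
    cur = x[..., None]
    for i in range(5):
        if i > 0:
            cur = pool(cur)
        cur = block(cur, f"enc{i}")
        grid[(i, 0)] = cur
    for j in range(1, 5):
        for i in range(0, 5 - j):
            skips = np.concatenate([grid[(i, jj)] for jj in range(j)], axis=-1)
            hw = skips.shape[1:3]
            u = up(grid[(i + 1, j - 1)], f"up{i}_{j}", hw)
            grid[(i, j)] = block(np.concatenate([skips, u], axis=-1), f"node{i}_{j}")
    ref_heads = [
        conv(grid[(0, j)], f"head{j}", 0).transpose(0, 3, 1, 2) for j in range(1, 5)
    ]
    for got, ref in zip(heads, ref_heads):
        assert np.allclose(got, ref, atol=1e-5)


def test_output_spatial_size_matches_input_for_divisible_sizes(micro_cfg, rng):
    model = build_model(micro_cfg)
    for size in (32, 48):
        heads = forward_logits(model, rng.random((1, size, size), dtype=np.float32))
        assert heads[0].shape[2:] == (size, size)


def test_forward_predict_contracts(micro_cfg, rng):
    model = build_model(micro_cfg, seed=2)
    img = rng.random((64, 64), dtype=np.float32)
    probs, labels = forward_predict(model, img)
    assert probs.shape == (6, 64, 64)
    assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-6)
    assert labels.shape == (64, 64) and labels.max() < 6
    # determinism
    probs2, labels2 = forward_predict(model, img)
    assert np.array_equal(probs, probs2) and np.array_equal(labels, labels2)


def test_ds_combine_last_reproduces_l4_head(micro_cfg, rng):
    import dataclasses

    img = rng.random((32, 32), dtype=np.float32)
    m_mean = build_model(micro_cfg, seed=4)
    m_last = build_model(dataclasses.replace(micro_cfg, ds_head_combine="last"), seed=0)
    m_last.load_state_dict(m_mean.state_dict())
    probs_last, _ = forward_predict(m_last, img)
    m_mean.eval()
    h4 = forward_logits(m_mean, img)[-1]
    from echoseg.lovasz import softmax_scores

    assert np.allclose(probs_last, softmax_scores(h4[0].transpose(1, 2, 0), axis=-1
                                                  ).transpose(2, 0, 1), atol=1e-6)


def test_argmax_tie_breaks_to_lower_class():
    probs = np.zeros((6, 2, 2))
    probs[2] = 0.5
    probs[4] = 0.5
    assert (probs.argmax(axis=0) == 2).all()


def test_checkpoint_roundtrip_identical_predictions(micro_cfg, tmp_path, rng):
    model = build_model(micro_cfg, seed=6)
    img = rng.random((2, 32, 32), dtype=np.float32)
    _, before = forward_predict(model, img)
    path = save_checkpoint(model, tmp_path / "m.npz")
    model2 = load_checkpoint(path)
    probs2, after = forward_predict(model2, img)
    assert np.array_equal(before, after)
    assert model2.cfg == micro_cfg


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        ModelConfig(decode_mode="L5")
    with pytest.raises(ValueError):
        ModelConfig(ppm_bins=(2, 2, 3))
    with pytest.raises(ValueError):
        ModelConfig(encoder_widths=(4, 8))
    model = build_model(ModelConfig(encoder_widths=MICRO_WIDTHS, ppm_bins=(1, 2)))
    with pytest.raises(ValueError):
        model(Tensor(np.zeros((1, 32, 32, 3))))  # wrong channel count
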