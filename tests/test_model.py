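"""Architecture tests: shape trace, parameter/MAC accounting, variants."""

import dataclasses

import numpy as np
import pytest

from microsleepnet import (
    ModelConfig,
    ablation_configs,
    analytic_parameter_count,
    build_model,
    count_macs,
    count_parameters,
    feature_block,
    load_checkpoint,
    receptive_field,
    receptive_field_probe,
    save_checkpoint,
    summarize,
)
from microsleepnet.nn import softmax


@pytest.fixture(scope="module")
def default_model():
    return build_model(seed=0).eval()


# ---------------------------------------------------------------------
# shape trace
# ---------------------------------------------------------------------

def test_shape_trace_matches_layer_table(default_model, rng):
    """Every block's output matches the published dimensions:
    lengths 3000 -> 1000 -> 333 -> 111 -> 37 -> 37, channels
    64/128/128/128/128, GAP (128, 1), logits (B, 5)."""
    x = rng.standard_normal((2, 1, 3000)).astype(np.float32)
    expected = [(64, 1000), (128, 333), (128, 111), (128, 37), (128, 37)]
    seen = []
    h = x
    for name, mod in default_model.features.steps:
        h = mod(h)
        if name.startswith("block"):
            seen.append(h.shape[1:])
    assert seen == expected
    assert h.shape == (2, 128, 37)          # post-fusion feature map
    pooled = default_model.head_pool(h)
    assert pooled.shape == (2, 128)         # GAP output (B, 128, 1) squeezed
    logits = default_model.classifier(pooled)
    assert logits.shape == (2, 5)


def test_fusion_layer_shapes(default_model, rng):
    x = rng.standard_normal((2, 128, 37)).astype(np.float32)
    h = default_model.features["dconv1_conv"](x)
    assert h.shape == (2, 32, 37)
    h = rng.standard_normal((2, 64, 37)).astype(np.float32)
    assert default_model.features["dconv3_conv"](h).shape == (2, 128, 37)


def test_feature_block_shapes(rng):
    out = feature_block(rng.standard_normal((2, 1, 3000)), block_index=1)
    assert out.shape == (2, 64, 1000)
    out = feature_block(rng.standard_normal((2, 64, 1000)), block_index=2)
    assert out.shape == (2, 128, 333)
    out = feature_block(rng.standard_normal((2, 128, 37)), block_index=5)
    assert out.shape == (2, 128, 37)        # block 5 is not pooled
    with pytest.raises(ValueError, match="channels"):
        feature_block(rng.standard_normal((2, 3, 3000)), block_index=1)


def test_posteriors_normalised_and_deterministic(default_model, rng):
    x = rng.standard_normal((2, 1, 3000)).astype(np.float32)
    p1 = default_model.predict_proba(x)
    p2 = default_model.predict_proba(x)
    np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(p1, p2)   # inference is deterministic


# ---------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------

def test_default_parameter_count_is_48226(default_model):
    assert count_parameters(default_model) == 48226
    assert analytic_parameter_count(ModelConfig()) == 48226


def test_attention_cost_is_93_parameters():
    without = ModelConfig(ecsa_enabled=False)
    assert analytic_parameter_count(ModelConfig()) \
        - analytic_parameter_count(without) == 93
    assert count_parameters(build_model(without)) == 48133


def test_linear_head_alone_is_645_parameters(default_model):
    head = default_model.classifier
    assert head.weight.size + head.bias.size == 128 * 5 + 5 == 645


@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
def test_analytic_count_matches_built_model_across_alpha(alpha):
    cfg = ModelConfig(width_multiplier_alpha=alpha)
    assert count_parameters(build_model(cfg)) == analytic_parameter_count(cfg)


@pytest.mark.parametrize("name", sorted(ablation_configs()))
def test_analytic_count_matches_built_model_across_ablations(name):
    cfg = ablation_configs()[name]
    assert count_parameters(build_model(cfg)) == analytic_parameter_count(cfg)


def test_width_multiplier_scales_parameters_monotonically():
    counts = [analytic_parameter_count(ModelConfig(width_multiplier_alpha=a))
              for a in (0.5, 1.0, 2.0)]
    assert counts[0] < counts[1] < counts[2]


def test_fc_head_variant_counts():
    """The flatten + linear head costs 128*37*5 + 5 parameters, giving the
    ~71.3k variant."""
    assert analytic_parameter_count(ModelConfig(head="FC")) == \
        48226 - 645 + (128 * 37 * 5 + 5)


# ---------------------------------------------------------------------
# MAC accounting
# ---------------------------------------------------------------------

def test_first_conv_macs_closed_form():
    """Standard conv k=3, C_in=1, C_out=64 at length 3000: 576,000 MACs."""
    rows = summarize(ModelConfig(ecsa_enabled=False))
    assert rows[0].macs == 3 * 3000 * 1 * 64 == 576000


def test_group_conv_macs_are_reduced_by_group_factor():
    grouped = summarize(ModelConfig(ecsa_enabled=False))
    standard = summarize(ModelConfig(ecsa_enabled=False,
                                     block_groups=(1, 1, 1, 1, 1)))
    for g_row, s_row in zip(grouped[1:5], standard[1:5]):
        assert s_row.macs == 64 * g_row.macs


def test_linear_head_macs(default_model):
    rows = summarize(default_model.cfg)
    assert rows[-1].macs == 128 * 5 == 640
    assert count_macs(default_model) == sum(r.macs for r in rows)


# ---------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------

@pytest.mark.parametrize("kernel,dilations,expected", [
    (3, (1, 2, 4), 15),
    (3, (1,), 3),
    (3, (1, 1), 5),
])
def test_receptive_field_closed_form_and_probe_agree(kernel, dilations,
                                                     expected):
    assert receptive_field(kernel, dilations) == expected
    assert receptive_field_probe(kernel, dilations, seed=0) == expected


def test_receptive_field_rejects_empty_dilations():
    with pytest.raises(ValueError, match="non-empty"):
        receptive_field(3, ())


# ---------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------

def test_zero_attention_weights_scale_each_block_by_one_quarter(rng):
    """With zeroed gate convolutions both attentions output coefficient
    0.5, so a block's output is exactly 0.25 x the attention-free path."""
    from microsleepnet.model import FeatureBlock

    cfg = ModelConfig()
    spec = cfg.block_plan()[1]
    block = FeatureBlock(spec, cfg, np.random.default_rng(0)).eval()
    x = rng.standard_normal((2, 64, 300)).astype(np.float32)
    block.eca.conv.weight.data[:] = 0.0
    block.spatial.conv.weight.data[:] = 0.0
    gated = block(x)
    block_no_att = FeatureBlock(dataclasses.replace(spec, ecsa=False), cfg,
                                np.random.default_rng(0)).eval()
    block_no_att.conv.weight.data = block.conv.weight.data
    plain = block_no_att(x)
    np.testing.assert_allclose(gated, 0.25 * plain, rtol=1e-5, atol=1e-6)


def test_grouped_conv_matches_standard_conv_with_block_diagonal_weights(rng):
    """A g-group convolution equals a dense convolution whose kernel is
    block-diagonal across the channel groups."""
    from microsleepnet import nn

    grouped = nn.Conv1d(8, 8, 3, padding=1, groups=4, rng=rng,
                        dtype=np.float64)
    dense = nn.Conv1d(8, 8, 3, padding=1, groups=1, rng=rng, dtype=np.float64)
    dense.weight.data[:] = 0.0
    for o in range(8):
        g = o // 2
        dense.weight.data[o, 2 * g:2 * g + 2, :] = grouped.weight.data[o]
    x = rng.standard_normal((2, 8, 16))
    np.testing.assert_allclose(grouped(x), dense(x), atol=1e-12)


def test_softmax_rows_sum_to_one(rng):
    p = softmax(rng.standard_normal((7, 5)) * 10)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_signal_batch_and_feature_map_invariants(rng):
    from microsleepnet import FeatureMap, SignalBatch

    batch = SignalBatch(rng.standard_normal((2, 1, 3000)))
    assert len(batch) == 2 and batch.sample_rate == 100.0
    with pytest.raises(ValueError, match="samples"):
        SignalBatch(rng.standard_normal((2, 1, 2999)))
    with pytest.raises(ValueError, match="1, samples"):
        SignalBatch(rng.standard_normal((2, 2, 3000)))
    fm = FeatureMap(rng.standard_normal((2, 128, 37)))
    assert fm.channels == 128 and fm.length == 37
    with pytest.raises(ValueError, match="3-D"):
        FeatureMap(rng.standard_normal((2, 128)))


# ---------------------------------------------------------------------
# configuration validation and checkpoints
# ---------------------------------------------------------------------

@pytest.mark.parametrize("kwargs,field_name", [
    ({"block_groups": (1, 64, 64, 64)}, "block_groups"),
    ({"dconv_dilations": (1, 2)}, "dconv"),
    ({"width_multiplier_alpha": -1.0}, "width_multiplier_alpha"),
    ({"head": "MLP"}, "head"),
    ({"fusion": "gated"}, "fusion"),
    ({"spatial_kernel": 6}, "spatial_kernel"),
    ({"dropout_rate": 1.5}, "dropout_rate"),
])
def test_invalid_config_errors_name_the_field(kwargs, field_name):
    with pytest.raises(ValueError, match=field_name):
        ModelConfig(**kwargs).validate()


def test_config_roundtrips_through_dict():
    cfg = ModelConfig(width_multiplier_alpha=0.5, fusion="normal")
    again = ModelConfig.from_dict(cfg.to_dict())
    assert again == cfg
    with pytest.raises(ValueError, match="unknown"):
        ModelConfig.from_dict({"block_channel": [64]})


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, rng):
    cfg = ModelConfig(width_multiplier_alpha=0.25)
    model = build_model(cfg, seed=3).eval()
    x = rng.standard_normal((3, 1, 3000)).astype(np.float32)
    before = model.predict_proba(x)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(restored.predict_proba(x), before)
    assert restored.cfg == cfg
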