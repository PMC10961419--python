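"""Structural contracts of the shuffle units, stems, multi-scale blocks and
the assembled models: shapes, permutation algebra, parameter accounting and
gradient flow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remshuffle import nn
from remshuffle.attention import AttentionConfig, adaptive_kernel_size
from remshuffle.backbone import (
    BasicUnit,
    DownUnit,
    MDFEM,
    ModelConfig,
    StageConfig,
    baseline_preset,
    build_model,
    build_stem,
    channel_shuffle,
    channel_split,
    count_parameters,
    parameter_manifest,
    rem_preset,
    shuffle_permutation,
    tiny_preset,
)
from remshuffle.nn import functional as F
from remshuffle.nn.tensor import Tensor

RNG = np.random.default_rng(99)
NO_ATTN = AttentionConfig(kind="none")


# ---------------------------------------------------------------------------
# permutation primitives
# ---------------------------------------------------------------------------

def test_channel_shuffle_interleaves_groups():
    x = np.arange(4).reshape(1, 4, 1, 1).astype(float)
    out = channel_shuffle(x, 2)
    np.testing.assert_array_equal(out[0, :, 0, 0], [0, 2, 1, 3])  # a,c,b,d


def test_channel_shuffle_identity_and_involution():
    x = RNG.standard_normal((2, 4, 3, 3))
    np.testing.assert_array_equal(channel_shuffle(x, 1), x)
    np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, 2), 2), x)


@given(st.integers(1, 8), st.integers(1, 8))
@settings(max_examples=40, deadline=None)
def test_channel_shuffle_is_a_bijection(groups, per_group):
    c = groups * per_group
    perm = shuffle_permutation(c, groups)
    assert sorted(perm.tolist()) == list(range(c))
    inv = np.argsort(perm)
    np.testing.assert_array_equal(perm[inv], np.arange(c))


def test_channel_shuffle_rejects_indivisible():
    with pytest.raises(ValueError):
        channel_shuffle(np.zeros((1, 5, 2, 2)), 2)


def test_channel_split_roundtrip_and_errors():
    x = RNG.standard_normal((2, 96, 4, 4))
    a, b = channel_split(x)
    assert a.shape[1] == b.shape[1] == 48
    np.testing.assert_array_equal(np.concatenate([a, b], axis=1), x)
    with pytest.raises(ValueError):
        channel_split(np.zeros((1, 3, 2, 2)))


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

def test_basic_unit_preserves_shape():
    unit = BasicUnit(96, AttentionConfig(), residual=True,
                     rng=np.random.default_rng(0))
    x = Tensor(RNG.standard_normal((2, 96, 28, 28)))
    assert unit(x).shape == (2, 96, 28, 28)
    with pytest.raises(ValueError):
        unit(Tensor(RNG.standard_normal((2, 48, 28, 28))))


def test_basic_unit_without_extras_matches_primitive_composition():
    """attention=none, residual=off reduces to split -> conv branch ->
    concat -> shuffle, recomposed here from the primitives."""
    unit = BasicUnit(16, NO_ATTN, residual=False, rng=np.random.default_rng(3))
    unit.eval()
    x = Tensor(RNG.standard_normal((2, 16, 6, 6)))
    out = unit(x).data
    left, right = channel_split(x)
    branch = unit.pw2(unit.dw(unit.pw1(right)))
    expected = channel_shuffle(
        np.concatenate([left.data, branch.data], axis=1), 2)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_basic_unit_residual_passes_input_through_zeroed_branch():
    unit = BasicUnit(8, NO_ATTN, residual=True, rng=np.random.default_rng(1))
    unit.eval()
    # zero every conv weight and BN scale on the right branch
    for _, p in unit.named_parameters():
        p.data[:] = 0.0
    x = Tensor(RNG.standard_normal((1, 8, 4, 4)))
    left, _ = channel_split(x)
    shuffled = channel_shuffle(
        np.concatenate([left.data, np.zeros_like(left.data)], axis=1), 2)
    np.testing.assert_allclose(unit(x).data, shuffled + x.data, atol=1e-12)


def test_down_unit_halves_space_and_sets_channels():
    for kind in ("none", "rm", "ra", "rc"):
        unit = DownUnit(96, 192, AttentionConfig(), kind,
                        rng=np.random.default_rng(0))
        out = unit(Tensor(RNG.standard_normal((2, 96, 28, 28))))
        assert out.shape == (2, 192, 14, 14)
    with pytest.raises(ValueError):
        DownUnit(96, 192, AttentionConfig(), "rx", np.random.default_rng(0))


def test_down_unit_residual_parameter_ordering():
    def params(kind):
        unit = DownUnit(96, 192, NO_ATTN, kind, np.random.default_rng(0))
        return sum(p.data.size for p in unit.parameters())

    assert params("rm") == params("ra")  # pooling is parameter-free
    assert params("rm") < params("rc")   # 3x3 full conv shortcut is not
    assert params("none") < params("rm")


# ---------------------------------------------------------------------------
# stems and multi-scale blocks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["a", "b", "c", "msfem"])
def test_every_stem_maps_to_quarter_resolution_24_channels(kind):
    stem = build_stem(kind, np.random.default_rng(0))
    out = stem(Tensor(RNG.standard_normal((1, 3, 224, 224))))
    assert out.shape == (1, 24, 56, 56)
    with pytest.raises(ValueError):
        stem(Tensor(RNG.standard_normal((1, 3, 30, 30))))


def test_stem_parameter_ordering():
    def params(kind):
        return sum(p.data.size
                   for p in build_stem(kind, np.random.default_rng(0)).parameters())

    p = {k: params(k) for k in ("a", "b", "c", "msfem")}
    assert p["msfem"] > p["c"] > p["a"]
    assert abs(p["b"] - p["a"]) < 10_000  # same order; 7x7 vs 3x3 conv, 3->24


def test_msfem_finite_on_constant_image():
    stem = build_stem("msfem", np.random.default_rng(0))
    out = stem(Tensor(np.full((1, 3, 64, 64), 0.5)))
    assert np.all(np.isfinite(out.data))


def test_mdfem_preserves_shape_and_matches_branch_composition():
    mdfem = MDFEM(384, np.random.default_rng(0))
    mdfem.eval()
    x = Tensor(RNG.standard_normal((1, 384, 7, 7)))
    out = mdfem(x)
    assert out.shape == (1, 384, 7, 7)
    expected = mdfem.fuse(
        F.concat_channels([mdfem.b3(x), mdfem.b5(x)])).data
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_disabling_mdfem_removes_its_parameters():
    with_m = count_parameters(build_model(tiny_preset(), seed=0))
    cfg = ModelConfig(stage=StageConfig((1, 1, 1), (24, 48, 96, 256)),
                      use_mdfem=False, num_classes=4, input_size=64)
    without = count_parameters(build_model(cfg, seed=0))
    assert "mdfem" in with_m.per_component
    assert "mdfem" not in without.per_component
    assert (with_m.total_params - without.total_params
            == with_m.per_component["mdfem"])


# ---------------------------------------------------------------------------
# whole models
# ---------------------------------------------------------------------------

def test_rem_preset_forward_contract_and_stage_shapes():
    model = build_model(rem_preset(), seed=0)
    x = Tensor(RNG.standard_normal((1, 3, 224, 224)))
    h = model.stem(x)
    assert h.shape == (1, 24, 56, 56)
    h = model.stage2(h)
    assert h.shape == (1, 96, 28, 28)
    h = model.stage3(h)
    assert h.shape == (1, 192, 14, 14)
    h = model.stage4(h)
    assert h.shape == (1, 384, 7, 7)
    logits = model(x)
    assert logits.shape == (1, 22)
    p = np.exp(logits.data) / np.exp(logits.data).sum()
    assert p.sum() == pytest.approx(1.0)


def test_parameter_counts_decrease_across_tuning_grid():
    grid = [
        ((3, 7, 3), (116, 232, 464, 1024)),
        ((3, 3, 3), (116, 232, 464, 1024)),
        ((2, 3, 2), (116, 232, 464, 1024)),
        ((1, 3, 1), (116, 232, 464, 1024)),
        ((2, 3, 2), (96, 192, 384, 1024)),
        ((2, 3, 2), (96, 192, 384, 768)),
    ]
    counts = [
        count_parameters(
            build_model(baseline_preset(repeats=r, out_channels=c), seed=0)
        ).total_params
        for r, c in grid
    ]
    assert all(a > b for a, b in zip(counts, counts[1:]))


def test_attention_toggle_changes_count_by_exactly_two_k_per_insertion():
    def cfg(kind):
        return ModelConfig(stage=StageConfig((2, 3, 2), (96, 192, 384, 1024)),
                           attention=AttentionConfig(kind=kind),
                           residual="rm", stem="a", use_mdfem=False)

    with_edca = count_parameters(build_model(cfg("edca"), seed=0)).total_params
    without = count_parameters(build_model(cfg("none"), seed=0)).total_params
    halves = []
    for out_c, reps in zip((96, 192, 384), (2, 3, 2)):
        halves += [out_c // 2] * (reps + 1)  # one down + reps basic per stage
    expected = sum(2 * adaptive_kernel_size(h) for h in halves)
    assert with_edca - without == expected


def test_rem_preset_has_more_parameters_than_tuned_baseline():
    rem = count_parameters(build_model(rem_preset(), seed=0)).total_params
    base = count_parameters(build_model(
        baseline_preset(repeats=(2, 3, 2),
                        out_channels=(96, 192, 384, 1024)), seed=0)).total_params
    assert rem > base


def test_count_parameters_linear_head_and_conservation():
    head = nn.Linear(1024, 22, rng=np.random.default_rng(0))
    assert sum(p.data.size for p in head.parameters()) == 1024 * 22 + 22
    rep = count_parameters(build_model(tiny_preset(), seed=0))
    assert sum(rep.per_component.values()) == rep.total_params
    assert rep.fp32_bytes == 4 * rep.total_params


def test_parameter_manifest_covers_every_parameter():
    model = build_model(tiny_preset(), seed=0)
    manifest = parameter_manifest(model)
    total = sum(int(np.prod(e["shape"])) for e in manifest)
    assert total == count_parameters(model).total_params
    assert len({e["name"] for e in manifest}) == len(manifest)


def test_gradient_flows_to_every_parameter_of_rem_preset():
    model = build_model(rem_preset(num_classes=5), seed=0)
    x = Tensor(RNG.standard_normal((2, 3, 224, 224)))
    loss = F.cross_entropy(model(x), np.array([0, 1]))
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, name
        assert np.all(np.isfinite(p.grad)), name
    stem_grads = [p.grad for n, p in model.named_parameters()
                  if n.startswith("stem")]
    assert any(np.any(g != 0) for g in stem_grads)


def test_model_config_validation_and_roundtrip():
    with pytest.raises(ValueError):
        ModelConfig(num_classes=1)
    with pytest.raises(ValueError):
        ModelConfig(residual="bad")
    with pytest.raises(ValueError):
        StageConfig(repeats=(0, 1, 1))
    with pytest.raises(ValueError):
        StageConfig(out_channels=(95, 192, 384, 1024))
    cfg = rem_preset(num_classes=7)
    back = ModelConfig.from_dict(cfg.to_dict())
    assert back == cfg
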