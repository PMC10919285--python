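"""Architecture contracts: shapes, parameter ordering, attention and
fusion block semantics, gradient flow and ablation equivalence."""

import numpy as np
import pytest

from musclesegkit.networks import (
    ASPPBlock,
    AttentionGate,
    CBAM,
    NetworkConfig,
    build_network,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from musclesegkit.nn import autograd as ag
from musclesegkit.nn.autograd import Tensor
from musclesegkit.nn.layers import Conv2d
from musclesegkit.nn.optim import segmentation_loss


def small_cfg(arch, **kw):
    defaults = dict(n_classes=3, base_width=4, depth=4, seed=3)
    defaults.update(kw)
    return NetworkConfig(arch=arch, **defaults)


# ---------------------------------------------------------------------------
# shape contract + counts


@pytest.mark.parametrize("arch", ["unet", "unetpp", "ffu", "affu"])
@pytest.mark.parametrize("size", [128, 256])
def test_output_matches_input_spatial_size(arch, size):
    net = build_network(NetworkConfig(arch=arch, n_classes=17, base_width=4,
                                      depth=5, seed=0)).eval()
    out = net(np.zeros((1, 1, size, size), dtype=np.float32))
    assert out.shape == (1, 17, size, size)


def test_odd_width_accepted_via_padding_policy():
    net = build_network(small_cfg("affu")).eval()
    out = net(np.zeros((1, 1, 48, 125), dtype=np.float32))
    assert out.shape == (1, 3, 48, 125)


def test_parameter_count_ordering():
    counts = {a: count_parameters(build_network(small_cfg(a)))
              for a in ["unet", "unetpp", "ffu", "affu"]}
    assert counts["ffu"] > counts["unet"]
    assert counts["affu"] > counts["ffu"]


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(arch="resnet")
    with pytest.raises(ValueError):
        NetworkConfig(depth=3)
    with pytest.raises(ValueError):
        NetworkConfig(n_classes=1)


def test_seeded_initialisation_is_deterministic():
    a = build_network(small_cfg("affu"))
    b = build_network(small_cfg("affu"))
    assert all(np.array_equal(p.data, q.data)
               for p, q in zip(a.parameters(), b.parameters()))


def test_inference_deterministic_given_weights():
    net = build_network(small_cfg("unet")).eval()
    x = np.random.default_rng(0).normal(size=(2, 1, 48, 48)).astype(np.float32)
    assert np.array_equal(net.predict_classes(x), net.predict_classes(x))


def test_unetpp_skip_node_count_matches_nested_topology():
    for depth in [4, 5]:
        net = build_network(NetworkConfig(arch="unetpp", n_classes=3,
                                          base_width=4, depth=depth, seed=0))
        assert net.n_skip_nodes == depth * (depth - 1) // 2


def test_checkpoint_roundtrip(tmp_path):
    net = build_network(small_cfg("ffu")).eval()
    x = np.random.default_rng(1).normal(size=(1, 1, 48, 48)).astype(np.float32)
    path = tmp_path / "ck.npz"
    save_checkpoint(net, path)
    back = load_checkpoint(path).eval()
    assert np.array_equal(net(x).data, back(x).data)


# ---------------------------------------------------------------------------
# attention gate


def test_attention_map_in_unit_interval_and_gating_semantics():
    rng = np.random.default_rng(0)
    gate = AttentionGate(skip_ch=4, gate_ch=8, rng=rng)
    skip = Tensor(rng.normal(size=(2, 4, 16, 16)).astype(np.float32))
    g = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
    amap = gate.attention_map(skip, g)
    assert amap.min() >= 0.0 and amap.max() <= 1.0
    out = gate(skip, g)
    # output = skip * alpha elementwise
    assert np.allclose(out.data, skip.data * amap, atol=1e-6)


def test_attention_extremes():
    rng = np.random.default_rng(0)
    gate = AttentionGate(skip_ch=4, gate_ch=4, rng=rng)
    skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    g = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
    # force the attention logit to +/- large values via the psi bias
    gate.psi.weight.data[:] = 0.0
    gate.psi.bias.data[:] = 60.0
    assert np.allclose(gate(skip, g).data, skip.data, atol=1e-5)  # alpha ~ 1
    gate.psi.bias.data[:] = -60.0
    assert np.abs(gate(skip, g).data).max() < 1e-5  # alpha ~ 0


# ---------------------------------------------------------------------------
# ASPP


def test_aspp_preserves_spatial_dims():
    rng = np.random.default_rng(0)
    block = ASPPBlock(4, 8, rates=(1, 2, 4), rng=rng).eval()
    x = Tensor(rng.normal(size=(1, 4, 20, 28)).astype(np.float32))
    assert block(x).shape == (1, 8, 20, 28)


def test_aspp_constant_input_constant_interior():
    rng = np.random.default_rng(0)
    block = ASPPBlock(2, 4, rates=(1,), rng=rng).eval()
    x = Tensor(np.full((1, 2, 16, 16), 0.7, dtype=np.float32))
    out = block(x).data
    interior = out[:, :, 2:-2, 2:-2]
    assert np.allclose(interior, interior[..., :1, :1], atol=1e-5)


def test_aspp_oversized_rate_degrades_with_warning():
    rng = np.random.default_rng(0)
    block = ASPPBlock(2, 4, rates=(8,), rng=rng).eval()
    x = Tensor(np.zeros((1, 2, 6, 6), dtype=np.float32))
    with pytest.warns(UserWarning, match="exceeds"):
        out = block(x)
    assert out.shape[2:] == (6, 6)


def test_empty_rates_rejected():
    with pytest.raises(ValueError):
        ASPPBlock(2, 4, rates=())


@pytest.mark.parametrize("rate", [1, 2, 4])
def test_dilated_conv_receptive_field_is_2r_plus_1(rate):
    """Impulse-response probe of one dilated 3x3 branch."""
    rng = np.random.default_rng(0)
    conv = Conv2d(1, 1, k=3, dilation=rate, rng=rng)
    conv.weight.data[:] = 1.0
    conv.bias.data[:] = 0.0
    n = 4 * rate + 5
    x = np.zeros((1, 1, n, n), dtype=np.float32)
    x[0, 0, n // 2, n // 2] = 1.0
    out = ag.conv2d(Tensor(x), conv.weight, conv.bias, dilation=rate).data[0, 0]
    ys, xs = np.nonzero(out)
    assert ys.max() - ys.min() + 1 == 2 * rate + 1
    assert xs.max() - xs.min() + 1 == 2 * rate + 1


# ---------------------------------------------------------------------------
# ablation + gradient flow


def test_affu_with_neutral_attention_equals_ffu():
    """Gates forced to 1 and CBAM to identity must reproduce FFU's output
    under shared weights."""
    affu = build_network(small_cfg("affu"))
    ffu = build_network(small_cfg("ffu", seed=99))
    shared = dict(affu.named_parameters())
    for name, p in ffu.named_parameters():
        p.data = shared[name].data.copy()
    affu.set_ablation(gates_passthrough=True, cbam_identity=True)
    x = np.random.default_rng(5).normal(size=(2, 1, 48, 48)).astype(np.float32)
    affu.train()
    ffu.train()
    assert np.array_equal(affu(x).data, ffu(x).data)


def test_fusion_head_and_gates_receive_gradient():
    net = build_network(small_cfg("affu"))
    x = np.random.default_rng(2).normal(size=(2, 1, 32, 32)).astype(np.float32)
    target = np.random.default_rng(3).integers(0, 3, size=(2, 32, 32))
    net.train()
    loss, _ = segmentation_loss(net(x), target, "ce+dice")
    net.zero_grad()
    loss.backward()
    groups = {
        "aspp": net.aspp,
        "merge": [net.merge],
        "cbam": [net.cbam],
        "gates": net.gates,
        "classifier": [net.classifier],
    }
    for name, mods in groups.items():
        norm = 0.0
        for m in mods:
            for p in m.parameters():
                if p.grad is not None:
                    norm += float((p.grad**2).sum())
        assert norm > 0.0, f"dead branch: {name}"


def test_cbam_identity_flag():
    rng = np.random.default_rng(0)
    cb = CBAM(8, rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    cb.identity = True
    assert np.array_equal(cb(x).data, x.data)
    cb.identity = False
    assert not np.array_equal(cb(x).data, x.data)
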