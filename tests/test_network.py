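"""Full network: construction, shape contracts, gradients, checkpoints."""

import numpy as np
import pytest

from mfsunet.errors import ConfigurationError, InvalidParameterError
from mfsunet.network import (NetworkConfig, build_network, load_checkpoint,
                             save_checkpoint)


def tiny_cfg(**kw):
    base = dict(depth=2, base_width=8, ssm_state_dim=4, ssm_expand=1, seed=0)
    base.update(kw)
    return NetworkConfig(**base)


def _tally_params(depth, widths, N, expand, k, c_in=1):
    """Independent layer-by-layer parameter tally (gated Mamba, conv k,
    FG on every skip, strided down / transposed up, 1x1 head)."""
    def branch(C):
        E = expand * C
        return ((C * E + E) * 2          # in and gate projections
                + k * E + E              # depthwise causal conv
                + E * E + E              # delta projection
                + 2 * E * N              # B and C projections
                + E * N + E              # A_log and skip
                + E * C + C)             # out projection

    def mpv(C):
        return 2 * C + 4 * branch(C) + 4 * C + 8 * C + 4 * C * C + C

    total = c_in * widths[0] + widths[0]                 # stem
    total += sum(mpv(w) for w in widths)                 # encoder blocks
    for i in range(depth - 1):                           # downsamples
        total += 4 * widths[i] * widths[i + 1] + widths[i + 1]
    for i in range(depth - 2, -1, -1):                   # decoder level i
        c, cd = widths[i], widths[i + 1]
        ci = max(1, c // 2)
        total += cd * 4 * c + 4 * c                      # transposed up
        total += (c * ci + ci) + (cd * ci + ci) + ci + 1  # FG gate
        total += 2 * c * c + c                           # fuse
        total += mpv(c)                                  # decoder block
    total += widths[0] + 1                               # head
    return total


class TestBuild:
    def test_deterministic_given_seed(self):
        n1 = build_network(tiny_cfg())
        n2 = build_network(tiny_cfg())
        s1, s2 = n1.state_dict(), n2.state_dict()
        assert s1.keys() == s2.keys()
        for k in s1:
            assert np.array_equal(s1[k], s2[k])

    def test_removing_fg_reduces_parameters(self):
        assert build_network(tiny_cfg(use_fg=False)).n_parameters() < \
            build_network(tiny_cfg()).n_parameters()

    def test_parameter_count_matches_independent_tally(self):
        cfg = NetworkConfig(depth=2, base_width=4, ssm_state_dim=2,
                            ssm_expand=1, seed=0)
        net = build_network(cfg)
        assert net.n_parameters() == _tally_params(2, (4, 8), N=2, expand=1, k=4)

    def test_depth_must_be_at_least_two(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(depth=1)

    def test_indivisible_spatial_dims_rejected(self, rng):
        net = build_network(tiny_cfg())
        with pytest.raises(ConfigurationError):
            net.forward_infer(rng.uniform(size=(1, 31, 31)))


class TestForward:
    def test_output_shape_and_range(self, rng):
        net = build_network(tiny_cfg())
        img = rng.uniform(size=(2, 32, 32))
        lab = (rng.uniform(size=(2, 32, 32)) > 0.8).astype(float)
        out, losses = net.forward_train(img, lab)
        assert out.prob_map.shape == (2, 32, 32)
        assert (out.prob_map > 0).all() and (out.prob_map < 1).all()
        for key in ("dice", "bce", "total"):
            assert np.isfinite(float(losses[key].data))

    def test_infer_deterministic_and_label_free(self, rng):
        net = build_network(tiny_cfg())
        img = rng.uniform(size=(1, 32, 32))
        a = net.forward_infer(img).prob_map
        b = net.forward_infer(img).prob_map
        assert np.array_equal(a, b)

    def test_train_path_equals_infer_when_slr_disabled(self, rng):
        net = build_network(tiny_cfg(use_slr=False))
        img = rng.uniform(size=(1, 32, 32))
        lab = (rng.uniform(size=(1, 32, 32)) > 0.8).astype(float)
        out, _ = net.forward_train(img, lab)
        assert np.array_equal(out.prob_map, net.forward_infer(img).prob_map)

    def test_slr_changes_training_features_only_with_errors(self, rng):
        """With the label equal to the current hard prediction M = 0, so the
        rectified features are a uniform (2 - lambda) rescale."""
        net = build_network(tiny_cfg())
        img = rng.uniform(size=(1, 32, 32))
        pred = (net.forward_infer(img).prob_map >= 0.5).astype(float)
        out, _ = net.forward_train(img, pred)
        assert out.aux is not None
        # aux is the pre-rectification map; M=0 so features scaled by 1.5
        assert np.array_equal((out.aux >= 0.5).astype(float), pred)

    def test_all_zero_image_finite(self):
        net = build_network(tiny_cfg())
        prob = net.forward_infer(np.zeros((1, 32, 32))).prob_map
        assert np.isfinite(prob).all()

    def test_unnormalized_input_warns_or_raises(self, rng):
        net = build_network(tiny_cfg())
        with pytest.warns(RuntimeWarning):
            net.forward_infer(rng.uniform(0, 255, size=(1, 32, 32)))
        net2 = build_network(tiny_cfg(strict_input_range="error"))
        with pytest.raises(InvalidParameterError):
            net2.forward_infer(rng.uniform(0, 255, size=(1, 32, 32)))

    def test_label_shape_mismatch(self, rng):
        net = build_network(tiny_cfg())
        with pytest.raises(InvalidParameterError):
            net.forward_train(rng.uniform(size=(1, 32, 32)),
                              np.zeros((1, 16, 16)))

    @pytest.mark.parametrize("downsample,upsample", [
        ("max_pool", "transposed_conv"), ("strided_conv", "interp_conv")])
    def test_alternative_resampling_modes(self, rng, downsample, upsample):
        net = build_network(tiny_cfg(downsample=downsample, upsample=upsample))
        prob = net.forward_infer(rng.uniform(size=(1, 32, 32))).prob_map
        assert prob.shape == (1, 32, 32) and np.isfinite(prob).all()


class TestGradients:
    def test_every_parameter_receives_gradient(self, rng):
        net = build_network(tiny_cfg())
        img = rng.uniform(size=(2, 32, 32))
        lab = (rng.uniform(size=(2, 32, 32)) > 0.7).astype(float)
        _, losses = net.forward_train(img, lab)
        losses["total"].backward()
        dead = [k for k, p in net.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestAblationWiring:
    def test_flags_reachable_from_config(self, rng):
        img = rng.uniform(size=(1, 32, 32))
        for flags in ({"use_mpv": False, "use_fg": False, "use_slr": False},
                      {"use_fg": False, "use_slr": False},
                      {"use_slr": False}, {}):
            net = build_network(tiny_cfg(**flags))
            assert np.isfinite(net.forward_infer(img).prob_map).all()

    def test_parameter_count_ladder(self):
        counts = [build_network(tiny_cfg(use_mpv=False, use_fg=False,
                                         use_slr=False)).n_parameters(),
                  build_network(tiny_cfg(use_fg=False,
                                         use_slr=False)).n_parameters(),
                  build_network(tiny_cfg(use_slr=False)).n_parameters(),
                  build_network(tiny_cfg()).n_parameters()]
        assert counts[0] < counts[1] <= counts[2] <= counts[3]


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, rng, tmp_path):
        net = build_network(tiny_cfg())
        img = rng.uniform(size=(1, 32, 32))
        want = net.forward_infer(img).prob_map
        save_checkpoint(net, tmp_path / "ck", extra={"epoch": np.array(3)})
        net2, extra = load_checkpoint(tmp_path / "ck")
        assert int(extra["epoch"]) == 3
        assert np.array_equal(net2.forward_infer(img).prob_map, want)


class TestOverfit:
    def test_single_phantom_overfits(self, small_phantom):
        """A tiny network driven hard on one phantom reaches near-perfect
        training Dice within 200 steps."""
        from mfsunet.metrics import evaluate_masks
        from mfsunet.optim import AdamW
        net = build_network(tiny_cfg())
        opt = AdamW(net.parameters(), lr=1e-2, weight_decay=0.0)
        img = small_phantom.image[None]
        lab = small_phantom.mask[None].astype(float)
        dice = 0.0
        for step in range(200):
            opt.zero_grad()
            out, losses = net.forward_train(img, lab)
            losses["total"].backward()
            opt.step()
            dice = evaluate_masks(out.prob_map[0] >= 0.5,
                                  small_phantom.mask).dice
            if dice > 0.99:
                break
        assert dice > 0.99
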