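"""Network structure: MIP/RIP contracts, forward shapes, parameter
counting, determinism and a short training smoke run."""

import numpy as np
import pytest

from vesseltopo import losses, network, patching
from vesseltopo.autodiff import as_tensor


class TestMipPool:
    def test_constant_tensor(self):
        x = np.full((1, 2, 4, 4, 4), 3.5, dtype=np.float32)
        out, rec = network.mip_pool(x)
        assert out.shape == (1, 2, 2, 2, 2)
        assert (out == 3.5).all()

    def test_spike_per_window(self, rng):
        x = np.zeros((1, 1, 4, 4, 4), dtype=np.float32)
        spikes = {}
        for wz in range(2):
            for wy in range(2):
                for wx in range(2):
                    dz, dy, dx = rng.integers(0, 2, size=3)
                    v = float(rng.random()) + 1.0
                    x[0, 0, 2 * wz + dz, 2 * wy + dy, 2 * wx + dx] = v
                    spikes[(wz, wy, wx)] = v
        out, rec = network.mip_pool(x)
        for (wz, wy, wx), v in spikes.items():
            assert out[0, 0, wz, wy, wx] == pytest.approx(v)

    def test_matches_window_max_oracle(self, rng):
        x = rng.normal(size=(2, 3, 4, 6, 8)).astype(np.float32)
        out, rec = network.mip_pool(x)
        for n in range(2):
            for c in range(3):
                for z in range(2):
                    for y in range(3):
                        for w in range(4):
                            win = x[n, c, 2 * z : 2 * z + 2, 2 * y : 2 * y + 2, 2 * w : 2 * w + 2]
                            assert out[n, c, z, y, w] == pytest.approx(win.max())

    def test_odd_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            network.mip_pool(rng.normal(size=(1, 1, 3, 4, 4)))

    def test_tie_break_lowest_linear_index(self):
        x = np.ones((1, 1, 2, 2, 2), dtype=np.float32)
        out, rec = network.mip_pool(x)
        assert rec["idx"][0, 0, 0, 0, 0] == 0


class TestRipUnpool:
    def test_round_trip_support_and_values(self, rng):
        x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
        pooled, rec = network.mip_pool(x)
        up = network.rip_unpool(pooled, rec)
        assert up.shape == x.shape
        nz = up != 0
        # support only at argmax positions; values equal window maxima
        assert nz.sum() <= pooled.size
        np.testing.assert_allclose(up[nz], x[nz])

    def test_sum_conserved(self, rng):
        x = rng.normal(size=(2, 2, 4, 6, 8)).astype(np.float32)
        pooled, rec = network.mip_pool(x)
        up = network.rip_unpool(pooled, rec)
        assert up.sum() == pytest.approx(pooled.sum(), rel=1e-5)

    def test_matches_scatter_oracle(self, rng):
        x = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        pooled, rec = network.mip_pool(x)
        up = network.rip_unpool(pooled, rec)
        oracle = np.zeros_like(x)
        for z in range(2):
            for y in range(2):
                for w in range(2):
                    win = x[0, 0, 2 * z : 2 * z + 2, 2 * y : 2 * y + 2, 2 * w : 2 * w + 2]
                    dz, dy, dx = np.unravel_index(win.argmax(), (2, 2, 2))
                    oracle[0, 0, 2 * z + dz, 2 * y + dy, 2 * w + dx] = win.max()
        np.testing.assert_allclose(up, oracle)

    def test_mismatched_record_rejected(self, rng):
        x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
        _, rec = network.mip_pool(x)
        with pytest.raises(ValueError):
            network.rip_unpool(rng.normal(size=(1, 3, 2, 2, 2)).astype(np.float32), rec)


def expected_parameter_count(cfg: network.ModelConfig) -> int:
    """Closed-form layer-by-layer parameter count, independent of the
    implementation's own bookkeeping."""

    def conv(cin, cout, k):
        return cout * cin * k**3 + cout

    def block(cin, cout):
        n = conv(cin, cout, 3) + conv(cout, cout, 3)
        if cin != cout:
            n += conv(cin, cout, 1)
        return n

    enc = [cfg.base_channels * 2**l for l in range(cfg.levels)]
    total = 0
    cin = 1
    for c in enc:
        total += block(cin, c)
        cin = c
    cprev = enc[-1]
    for j in range(cfg.levels):
        e = cfg.levels - 1 - j
        cout = enc[max(e - 1, 0)]
        total += block(cprev + enc[e], cout)
        cprev = cout
    c_aux = enc[-1] if cfg.shared_decoder_levels == 0 else enc[cfg.levels - 1 - cfg.shared_decoder_levels]
    for j in range(cfg.shared_decoder_levels, cfg.levels):
        e = cfg.levels - 1 - j
        cout = enc[max(e - 1, 0)]
        total += 2 * block(c_aux, cout)  # the two exclusive aux stacks
        c_aux = cout
    total += 3 * conv(enc[0], 1, 1)  # three 1x1x1 heads
    total += enc[-1] * cfg.domain_hidden + cfg.domain_hidden  # fc1
    total += cfg.domain_hidden * cfg.n_domains + cfg.n_domains  # fc2
    return total


class TestBuildModel:
    CFG = network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16), n_domains=3)

    def test_forward_shape_contract(self):
        model = network.build_model(self.CFG, seed=0)
        out = model.forward(np.zeros((2, 1, 8, 16, 16), np.float32), train=False)
        for key in ("main", "aux_distance", "aux_skeleton"):
            assert out[key].data.shape == (2, 1, 8, 16, 16)
        assert out["domain"].data.shape == (2, 3)
        np.testing.assert_allclose(out["domain"].data.sum(axis=1), 1.0, atol=1e-6)
        assert (out["aux_distance"].data >= 0).all()
        assert (out["main"].data >= 0).all() and (out["main"].data <= 1).all()

    def test_parameter_count_deterministic(self):
        a = network.build_model(self.CFG, seed=0)
        b = network.build_model(self.CFG, seed=0)
        assert network.count_parameters(a) == network.count_parameters(b)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    @pytest.mark.parametrize(
        "cfg",
        [
            CFG,
            network.ModelConfig(levels=2, base_channels=8, patch_shape=(8, 16, 16),
                                shared_decoder_levels=1, n_domains=4),
            network.ModelConfig(levels=4, base_channels=4, patch_shape=(16, 32, 32),
                                shared_decoder_levels=2, n_domains=2),
            network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16),
                                shared_decoder_levels=0, n_domains=3),
        ],
        ids=["tiny", "two-level", "four-level", "no-shared"],
    )
    def test_parameter_count_matches_closed_form(self, cfg):
        model = network.build_model(cfg, seed=1)
        assert network.count_parameters(model) == expected_parameter_count(cfg)

    def test_inference_deterministic(self, rng):
        model = network.build_model(self.CFG, seed=3)
        x = rng.normal(size=(1, 1, 8, 16, 16)).astype(np.float32)
        a = model.forward(x, train=False)["main"].data
        b = model.forward(x, train=False)["main"].data
        np.testing.assert_array_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            network.ModelConfig(levels=3, patch_shape=(12, 16, 16))  # 12 % 8 != 0
        with pytest.raises(ValueError):
            network.ModelConfig(levels=3, shared_decoder_levels=3)
        with pytest.raises(ValueError):
            network.ModelConfig(n_domains=1)

    def test_save_load_round_trip(self, tmp_path, rng):
        model = network.build_model(self.CFG, seed=4)
        x = rng.normal(size=(1, 1, 8, 16, 16)).astype(np.float32)
        before = model.forward(x, train=False)["main"].data
        model.save(tmp_path / "ckpt.npz")
        back = network.MultiTaskVesselNet.load(tmp_path / "ckpt.npz")
        after = back.forward(x, train=False)["main"].data
        np.testing.assert_array_equal(before, after)


def _toy_patches(n=8, shape=(8, 16, 16), seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        lab = np.zeros(shape, np.float32)
        lab[3:5, 4:12, 4:12] = 1
        img = lab * 1.5 + rng.normal(0, 0.3, size=shape).astype(np.float32)
        sk = np.zeros(shape, np.float32)
        sk[4, 8, 4:12] = 1
        recs.append(
            patching.PatchRecord(
                image=img, label=lab, skeleton=sk,
                distance=lab.copy(), origin=(0, 0, 0), domain_index=i % 3,
            )
        )
    return recs


class TestTraining:
    def test_smoke_run_finite_and_improving(self):
        cfg = network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16), n_domains=3)
        model = network.build_model(cfg, seed=0)
        patches = _toy_patches()
        hist = network.train_model(
            model,
            patches,
            loss_cfg=losses.LossConfig(reduction="mean"),
            train_cfg=network.TrainConfig(epochs=10, batch_size=4, lr=1e-3, seed=0),
            val_patches=patches[:2],
        )
        assert len(hist) == 10
        assert np.isfinite(hist["total"]).all()
        assert hist["total"].iloc[-1] < hist["total"].iloc[0]
        assert {"theta1", "theta2", "theta3", "dcl", "val_dice", "val_tc"} <= set(hist.columns)

    def test_empty_dataset_rejected(self):
        cfg = network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16))
        model = network.build_model(cfg, seed=0)
        with pytest.raises(ValueError):
            network.train_model(model, [])

    def test_training_deterministic_under_seed(self):
        cfg = network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16), n_domains=3)
        patches = _toy_patches(4)
        runs = []
        for _ in range(2):
            model = network.build_model(cfg, seed=1)
            hist = network.train_model(
                model, patches,
                loss_cfg=losses.LossConfig(reduction="mean"),
                train_cfg=network.TrainConfig(epochs=2, batch_size=2, lr=1e-3, seed=5),
            )
            runs.append(hist["total"].to_numpy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestPredictVolume:
    def test_output_shapes_and_stitch_consistency(self, rng):
        from vesseltopo.core import VolumeImage

        cfg = network.ModelConfig(levels=3, base_channels=4, patch_shape=(8, 16, 16))
        model = network.build_model(cfg, seed=0)
        v = VolumeImage(rng.normal(size=(10, 20, 18)))
        prob, seg = network.predict_volume(model, v)
        assert prob.data.shape == (10, 20, 18)
        assert seg.data.shape == (10, 20, 18)
        # the stitched probability at a voxel equals the forward output of
        # the unique tile containing it
        from vesseltopo.core import normalize_intensity

        vn = normalize_intensity(v)
        tiles, origins, _ = patching.tile_volume(vn.data, (8, 16, 16))
        out0 = model.forward(tiles[0][None, None].astype(np.float32), train=False)["main"].data[0, 0]
        np.testing.assert_allclose(prob.data[:8, :16, :16], out0[: 8, :16, :16], atol=1e-6)
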