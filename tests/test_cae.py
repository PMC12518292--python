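"""Architecture bookkeeping: latent partitioning, fusion dimensions, group passes."""

import numpy as np
import pytest

from phenocae.cae import (AEModel, CAEModel, GroupLayout, LatentConfig,
                          assemble_replicate_latent, build_groups,
                          fused_indices, fused_length, index_matrix,
                          load_checkpoint, save_checkpoint)

SMALL_HIDDEN = (32, 24, 16)


def small_cae(input_dim=30, latent=LatentConfig(3, 2, 1), layout=GroupLayout(3, 2),
              seed=0, dtype=np.float64):
    return CAEModel(input_dim, latent, layout, seed=seed,
                    encoder_hidden=SMALL_HIDDEN, decoder_hidden=SMALL_HIDDEN,
                    dtype=dtype)


class TestLayout:
    def test_n_images(self):
        assert GroupLayout(5, 2).n_images == 10
        assert GroupLayout(1, 1).n_images == 1

    def test_env_major_replicate_minor(self):
        layout = GroupLayout(5, 2)
        assert [layout.env_of(j) for j in range(10)] == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        assert [layout.micro_of(j) for j in range(10)] == list(range(10))

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            GroupLayout(2, 2).env_of(4)


class TestFusedBookkeeping:
    def test_default_config_lengths(self):
        # (zg, ze, zp) = (6, 6, 1), E = 5, N = 10: fused input 130, output 46
        latent, layout = LatentConfig(6, 6, 1), GroupLayout(5, 2)
        assert layout.n_images * latent.d == 130
        assert fused_length(latent, layout) == 46

    def test_degenerate_layout(self):
        latent = LatentConfig(6, 6, 1)
        assert fused_length(latent, GroupLayout(1, 1)) == latent.d

    def test_replicate_mapping_table(self):
        # E = 5, R = 2: the 5th image (env 3, replicate 1) reads macro block 3
        # and micro block 5; replicates of one environment share the macro block
        latent, layout = LatentConfig(6, 6, 1), GroupLayout(5, 2)
        fused = np.arange(fused_length(latent, layout), dtype=float)
        fifth = assemble_replicate_latent(fused, 4, latent, layout)
        assert fifth.environment_index == 2  # 3rd environment, 0-based
        assert fifth.micro_index == 4  # 5th micro block, 0-based
        np.testing.assert_array_equal(fifth.ze, fused[6 + 2 * 6: 6 + 3 * 6])
        np.testing.assert_array_equal(fifth.zp, fused[6 + 5 * 6 + 4: 6 + 5 * 6 + 5])

        first = assemble_replicate_latent(fused, 0, latent, layout)
        second = assemble_replicate_latent(fused, 1, latent, layout)
        np.testing.assert_array_equal(first.zg, second.zg)
        np.testing.assert_array_equal(first.ze, second.ze)
        assert not np.array_equal(first.zp, second.zp)
        assert first.vector.shape == (latent.d,)

    def test_blocks_tile_fused_vector_exactly_once(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            latent = LatentConfig(*rng.integers(1, 8, size=3))
            layout = GroupLayout(int(rng.integers(2, 6)), int(rng.integers(1, 4)))
            total = fused_length(latent, layout)
            assert total == latent.zg + layout.n_environments * latent.ze \
                + layout.n_images * latent.zp
            idx = index_matrix(latent, layout)
            counts = np.bincount(idx.ravel(), minlength=total)
            # Zg appears in every row; each Ze block in R rows; each Zp once
            assert (counts[:latent.zg] == layout.n_images).all()
            ze_region = counts[latent.zg:latent.zg + layout.n_environments * latent.ze]
            assert (ze_region == layout.n_replicates).all()
            assert (counts[latent.zg + layout.n_environments * latent.ze:] == 1).all()

    def test_wrong_fused_length_rejected(self):
        with pytest.raises(ValueError):
            assemble_replicate_latent(np.zeros(10), 0, LatentConfig(6, 6, 1),
                                      GroupLayout(5, 2))


class TestEncoderDecoder:
    def test_encode_output_width(self):
        model = small_cae()
        out = model.encode(np.zeros(30))
        assert out.shape == (model.latent.d,)

    def test_default_stack_widths(self):
        model = CAEModel(1452, LatentConfig(6, 6, 1), GroupLayout(5, 2))
        assert model.encoder.widths == [1452, 2200, 2000, 1000, 13]
        assert model.decoder.widths == [13, 2024, 3000, 2200, 1452]

    def test_zero_weights_give_zero_encoding_and_half_decoding(self):
        model = small_cae()
        for layer in model.encoder.layers + model.decoder.layers:
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        np.testing.assert_array_equal(model.encode(np.ones(30)), 0.0)
        np.testing.assert_array_equal(model.decode(np.zeros(model.latent.d)), 0.5)

    def test_decode_in_open_unit_interval(self, rng):
        model = small_cae()
        out = model.decode(rng.normal(size=(8, model.latent.d)))
        assert out.shape == (8, 30)
        assert (out > 0).all() and (out < 1).all()

    def test_deterministic(self, rng):
        model = small_cae()
        x = rng.normal(size=30)
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_length_mismatch_rejected(self):
        model = small_cae()
        with pytest.raises(ValueError):
            model.encode(np.zeros(29))
        with pytest.raises(ValueError):
            model.decoder.forward(np.zeros((1, model.latent.d + 1)))


class TestGroupForward:
    def test_shapes(self, rng):
        model = small_cae()
        x = rng.uniform(size=(model.layout.n_images, 30))
        recon, fused, lat = model.forward_group(x)
        assert recon.shape == x.shape
        assert fused.shape == (fused_length(model.latent, model.layout),)
        assert lat.shape == (model.layout.n_images, model.latent.d)

    def test_zg_and_ze_sharing_bitwise(self, rng):
        model = small_cae(layout=GroupLayout(3, 2))
        x = rng.uniform(size=(2, 6, 30))
        _, _, lat = model.forward_group(x)
        zg = lat[..., :model.latent.zg]
        ze = lat[..., model.latent.zg:model.latent.zg + model.latent.ze]
        for b in range(2):
            for j in range(6):
                np.testing.assert_array_equal(zg[b, j], zg[b, 0])
                np.testing.assert_array_equal(ze[b, j], ze[b, (j // 2) * 2])

    def test_swapping_replicates_swaps_zp_and_recon_only(self, rng):
        """With a replicate-symmetric fusion (mean-pool Zg/Ze, per-position
        Zp), swapping the two replicates of environment 1 swaps their Zp
        blocks and reconstructions and leaves Zg/Ze untouched. A dense
        trained fusion is not permutation-equivariant, so the property is
        checked on this explicit construction of the slicing bookkeeping."""
        from phenocae.cae import fused_length, index_matrix
        layout = GroupLayout(3, 2)
        model = small_cae(layout=layout)
        latent = model.latent
        zg, ze, zp, d = latent.zg, latent.ze, latent.zp, latent.d
        n = layout.n_images
        w = np.zeros((n * d, fused_length(latent, layout)))
        for pos in range(n):
            base = pos * d
            for i in range(zg):  # Zg: mean over all positions
                w[base + i, i] = 1.0 / n
            e = layout.env_of(pos)
            for i in range(ze):  # Ze_e: mean over the environment's replicates
                w[base + zg + i, zg + e * ze + i] = 1.0 / layout.n_replicates
            for i in range(zp):  # Zp_pos: that position's own slice
                w[base + zg + ze + i, zg + layout.n_environments * ze + pos * zp + i] = 1.0
        model.fusion.layers[0].W[...] = w
        model.fusion.layers[0].b[...] = 0.0

        x = rng.uniform(size=(6, 30))
        swapped = x.copy()
        swapped[[0, 1]] = swapped[[1, 0]]  # swap replicates of environment 1
        r1, _, l1 = model.forward_group(x)
        r2, _, l2 = model.forward_group(swapped)
        np.testing.assert_allclose(l1[0, :zg + ze], l2[0, :zg + ze], atol=1e-12)
        np.testing.assert_allclose(l1[0, zg + ze:], l2[1, zg + ze:], atol=1e-12)
        np.testing.assert_allclose(r1[0], r2[1], atol=1e-12)
        np.testing.assert_allclose(r1[1], r2[0], atol=1e-12)
        np.testing.assert_allclose(r1[2:], r2[2:], atol=1e-12)

    def test_incomplete_group_rejected(self, rng):
        model = small_cae()
        with pytest.raises(ValueError):
            model.forward_group(rng.uniform(size=(5, 30)))


class TestAEBaseline:
    def test_latent_width_matches_cae(self, rng):
        latent = LatentConfig(6, 6, 1)
        model = AEModel(30, latent, encoder_hidden=SMALL_HIDDEN,
                        decoder_hidden=SMALL_HIDDEN)
        z, recon = model.forward(rng.uniform(size=30))
        assert z.shape == (13,)
        assert recon.shape == (30,)
        assert (recon > 0).all() and (recon < 1).all()


class TestBuildGroups:
    def test_complete_grouping(self, tiny_dataset):
        from phenocae.imaging import feature_matrix
        feats = feature_matrix(tiny_dataset.images)
        grouped = build_groups(feats, tiny_dataset.metadata, GroupLayout(5, 2))
        assert grouped.x.shape == (8, 10, 1452)
        assert grouped.dropped_genotypes == []
        assert grouped.environment_ids == [f"E{i}" for i in range(1, 6)]

    def test_incomplete_genotype_dropped(self, tiny_dataset):
        from phenocae.imaging import feature_matrix
        feats = feature_matrix(tiny_dataset.images)
        meta = tiny_dataset.metadata
        keep = ~((meta["genotype_id"] == "G002") & (meta["environment_id"] == "E3")
                 & (meta["replicate_id"] == 2))
        grouped = build_groups(feats[keep.to_numpy()], meta[keep], GroupLayout(5, 2))
        assert grouped.dropped_genotypes == ["G002"]
        assert grouped.x.shape == (7, 10, 1452)


class TestCheckpoint:
    def test_cae_round_trip(self, tmp_path, rng):
        model = small_cae(seed=3)
        x = rng.uniform(size=(model.layout.n_images, 30))
        recon, fused, _ = model.forward_group(x)
        save_checkpoint(model, tmp_path / "m.npz", extra={"note": "fit"})
        loaded, extra = load_checkpoint(tmp_path / "m.npz")
        assert extra == {"note": "fit"}
        recon2, fused2, _ = loaded.forward_group(x.astype(loaded.dtype))
        np.testing.assert_allclose(fused2, fused, atol=1e-6)
        np.testing.assert_allclose(recon2, recon, atol=1e-6)

    def test_ae_round_trip(self, tmp_path, rng):
        model = AEModel(20, LatentConfig(2, 2, 1), seed=1,
                        encoder_hidden=SMALL_HIDDEN, decoder_hidden=SMALL_HIDDEN)
        x = rng.uniform(size=(4, 20))
        z, _ = model.forward(x)
        save_checkpoint(model, tmp_path / "ae.npz")
        loaded, _ = load_checkpoint(tmp_path / "ae.npz")
        z2, _ = loaded.forward(x)
        np.testing.assert_allclose(z2, z, atol=1e-6)
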