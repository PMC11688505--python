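import numpy as np
import pytest

from gbpct import n2i
from gbpct.acquisition import AcquisitionGeometry, simulate_stepping
from gbpct.network import NetConfig
from gbpct.phantom import make_phantom
from gbpct.recon import reconstruct_attenuation
from gbpct.retrieval import retrieve


@pytest.fixture(scope="module")
def small_noisy_sino():
    ph = make_phantom((32, 32), seed=5)
    geo = AcquisitionGeometry(n_angles=32, seed=9)
    return retrieve(simulate_stepping(ph, geo, noise=True))


@pytest.fixture(scope="module")
def small_clean_sino():
    ph = make_phantom((32, 32), seed=5)
    geo = AcquisitionGeometry(n_angles=32)
    return retrieve(simulate_stepping(ph, geo, noise=False))


class TestSplitSinogram:
    def test_interleaved_rule_with_eight_angles(self, small_noisy_sino):
        sino = small_noisy_sino
        idx = n2i.split_sinogram(sino, 2)
        np.testing.assert_array_equal(idx[0], np.arange(0, 32, 2))
        np.testing.assert_array_equal(idx[1], np.arange(1, 32, 2))

    def test_uneven_split_sizes_differ_by_at_most_one(self):
        import gbpct.retrieval as r

        sino = r.SinogramPair(
            transmission=np.ones((9, 8)),
            dphase=np.zeros((9, 8)),
            angles=np.arange(9) * np.pi / 9,
        )
        idx = n2i.split_sinogram(sino, 4)
        assert sorted(len(i) for i in idx) == [2, 2, 2, 3]

    def test_union_and_disjointness_by_exhaustive_scan(self):
        import gbpct.retrieval as r

        for n_angles in range(12, 41, 7):
            sino = r.SinogramPair(
                transmission=np.ones((n_angles, 4)),
                dphase=np.zeros((n_angles, 4)),
                angles=np.arange(n_angles) * np.pi / n_angles,
            )
            for k in range(2, 7):
                subsets = [set(i.tolist()) for i in n2i.split_sinogram(sino, k)]
                union = set().union(*subsets)
                assert union == set(range(n_angles))
                assert sum(len(s) for s in subsets) == n_angles  # pairwise disjoint

    def test_oversized_k_rejected(self, small_noisy_sino):
        with pytest.raises(ValueError):
            n2i.split_sinogram(small_noisy_sino, 17)


class TestTrainingPairs:
    def test_two_splits_swap_roles(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        pairs = n2i.make_training_pairs(splits)
        assert len(pairs) == 2
        np.testing.assert_array_equal(pairs[0][0], splits.subsets[1].data)
        np.testing.assert_array_equal(pairs[0][1], splits.subsets[0].data)
        np.testing.assert_array_equal(pairs[1][0], splits.subsets[0].data)
        np.testing.assert_array_equal(pairs[1][1], splits.subsets[1].data)

    def test_four_splits_use_mean_of_three_as_input(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 4, "attenuation")
        pairs = n2i.make_training_pairs(splits)
        assert len(pairs) == 4
        expected = np.mean([splits.subsets[i].data for i in (1, 2, 3)], axis=0)
        np.testing.assert_allclose(pairs[0][0], expected)

    def test_noiseless_pairs_collapse_toward_full_reconstruction(self, small_clean_sino):
        """Without noise the pairs carry no training signal: the mean of the
        targets IS the full reconstruction (angle additivity, exact), and
        each individual pair differs from it only by angular discretization
        of its 8-angle subset."""
        splits = n2i.make_split_set(small_clean_sino, 4, "attenuation")
        full = reconstruct_attenuation(small_clean_sino).data
        pairs = n2i.make_training_pairs(splits)
        np.testing.assert_allclose(
            np.mean([t for _, t in pairs], axis=0), full, atol=1e-12
        )
        scale = np.abs(full).max()
        for inp, tgt in pairs:
            assert np.abs(inp - full).max() < 0.3 * scale
            assert np.abs(tgt - full).max() < 0.8 * scale

    def test_one_to_x_strategy_swaps_input_and_target(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 4, "attenuation")
        x1 = n2i.make_training_pairs(splits, strategy="X:1")
        inv = n2i.make_training_pairs(splits, strategy="1:X")
        for (a_in, a_tg), (b_in, b_tg) in zip(x1, inv):
            np.testing.assert_array_equal(a_in, b_tg)
            np.testing.assert_array_equal(a_tg, b_in)


class TestTraining:
    def test_identical_input_target_pairs_reach_tiny_loss(self, small_clean_sino):
        """With input == target a near-identity start converges to loss < 1e-6
        (the network only has to drive its residual head to zero)."""
        full = reconstruct_attenuation(small_clean_sino).data
        run = n2i.train(
            [(full, full), (full, full)], epochs=30, seed=0,
            net_config=NetConfig(depth=2, width=4),
        )
        assert run.loss_history[-1] < 1e-6

    def test_fixed_seed_reproduces_loss_history(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        pairs = n2i.make_training_pairs(splits)
        cfg = NetConfig(depth=2, width=4)
        a = n2i.train(pairs, epochs=4, seed=3, net_config=cfg)
        b = n2i.train(pairs, epochs=4, seed=3, net_config=cfg)
        assert a.loss_history == b.loss_history
        for pa, pb in zip(a.model.parameters(), b.model.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_checkpoint_thinning(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=7, seed=0,
            net_config=NetConfig(depth=1, width=2), checkpoint_every=3,
        )
        assert run.checkpoint_epochs == [2, 5, 6]  # every 3rd plus the last


class TestDenoise:
    def test_identity_network_returns_full_reconstruction(self, small_clean_sino):
        """With f = identity the split-averaged output collapses, by angle
        additivity, to the full-angle FBP."""
        splits = n2i.make_split_set(small_clean_sino, 4, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=1, seed=0,
            net_config=NetConfig(depth=1, width=2), K=4,
        )
        run.model.head_w[:] = 0.0  # exact identity
        run.model.head_b[:] = 0.0
        out = n2i.denoise(run, splits)
        full = reconstruct_attenuation(small_clean_sino).data
        np.testing.assert_allclose(out.data, full, atol=1e-10)
        assert out.signal_type == "attenuation"

    def test_k_mismatch_rejected(self, small_noisy_sino):
        splits2 = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        splits4 = n2i.make_split_set(small_noisy_sino, 4, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits2), epochs=1, seed=0,
            net_config=NetConfig(depth=1, width=2), K=2,
        )
        with pytest.raises(ValueError, match="K="):
            n2i.denoise(run, splits4)


class TestSelectEpoch:
    def test_single_checkpoint_returns_it(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=1, seed=0,
            net_config=NetConfig(depth=1, width=2), K=2,
        )
        ref = reconstruct_attenuation(small_noisy_sino).data
        assert n2i.select_epoch(run, splits, ref) == 0

    def test_tie_resolves_to_earliest(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=1, seed=0,
            net_config=NetConfig(depth=1, width=2), K=2,
        )
        # duplicate the sole checkpoint: identical scores, earliest must win
        run.checkpoints = [run.checkpoints[0], run.checkpoints[0]]
        run.checkpoint_epochs = [0, 1]
        ref = reconstruct_attenuation(small_noisy_sino).data
        assert n2i.select_epoch(run, splits, ref) == 0

    def test_selected_psnr_at_least_final_epoch(self, small_noisy_sino):
        from gbpct.iqa import psnr

        ph = make_phantom((32, 32), seed=5)
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=30, seed=1, K=2,
            net_config=NetConfig(depth=2, width=4),
        )
        best = n2i.select_epoch(run, splits, ph.mu, metric="psnr")
        run.model.set_parameters(run.checkpoints[best])
        best_psnr = psnr(n2i.denoise(run, splits).data, ph.mu)
        run.model.set_parameters(run.checkpoints[-1])
        final_psnr = psnr(n2i.denoise(run, splits).data, ph.mu)
        assert best_psnr >= final_psnr

    def test_unknown_metric_rejected(self, small_noisy_sino):
        splits = n2i.make_split_set(small_noisy_sino, 2, "attenuation")
        run = n2i.train(
            n2i.make_training_pairs(splits), epochs=1, seed=0,
            net_config=NetConfig(depth=1, width=2), K=2,
        )
        with pytest.raises(ValueError, match="unknown metric"):
            n2i.select_epoch(run, splits, np.zeros((32, 32)), metric="vibes")
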