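import numpy as np
import pytest

from qseg.encoder import EncoderConfig, ObservationSet, SetCodec, encode
from qseg.errors import (
    ConfigurationError,
    ContractViolationError,
    InvalidArgumentError,
    ShapeError,
)
from qseg.phantom import DWIVolume, build_phantom, default_scheme, simulate_acquisition
from qseg.segmenter import (
    LossConfig,
    SegNet2D,
    SegTrainConfig,
    TrainScheme,
    assemble_slice_input,
    boundary_map,
    compute_class_weights,
    embed_volume,
    load_segnet,
    predict_segmentation,
    prepare_training_volume,
    save_segnet,
    segmentation_loss,
    train_view,
)


@pytest.fixture(scope="module")
def codec():
    return SetCodec(EncoderConfig(L=4, hidden_width=8, pre_depth=2, dec_depth=2), seed=1)


@pytest.fixture(scope="module")
def tiny_setup(codec):
    """A 32^3 noiseless phantom with a 12-direction scheme."""
    scheme = default_scheme(12, n_b0=2, seed=3)
    phantom = build_phantom((32, 32, 32), seed=4)
    dwi = simulate_acquisition(phantom, scheme, noise_sigma=0.0, seed=0)
    return scheme, phantom, dwi


class TestComputeClassWeights:
    def test_equal_frequencies(self):
        labels = np.array([0, 0, 1, 1])
        np.testing.assert_allclose(compute_class_weights(labels, 2), [1.0, 1.0])

    def test_derived_formula(self):
        # frequencies (0.5, 0.3, 0.2) -> weights (0.6, 1.0, 1.5)
        labels = np.repeat([0, 1, 2], [5, 3, 2])
        np.testing.assert_allclose(compute_class_weights(labels, 3), [0.6, 1.0, 1.5])

    def test_rarest_class_largest_weight(self, rng):
        labels = rng.choice(4, p=[0.6, 0.25, 0.1, 0.05], size=2000)
        w = compute_class_weights(labels, 4)
        assert np.argmax(w) == np.argmin(np.bincount(labels, minlength=4))

    def test_missing_class_listed(self):
        with pytest.raises(ConfigurationError, match=r"\[2, 3\]"):
            compute_class_weights(np.array([0, 1]), 4)


class TestSegmentationLoss:
    def test_perfect_one_hot_is_zero(self):
        labels = np.array([[0, 1], [1, 0]])
        probs = np.eye(2)[labels]
        cfg = LossConfig(np.ones(2))
        assert segmentation_loss(probs, labels, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_s(self):
        s = 4
        labels = np.zeros((3, 3), dtype=int)
        probs = np.full((3, 3, s), 1.0 / s)
        cfg = LossConfig(np.ones(s), dice_weight=0.0)
        assert segmentation_loss(probs, labels, cfg) == pytest.approx(np.log(s), rel=1e-9)

    def test_edge_boost_increases_loss(self):
        labels = np.array([[0, 0, 1, 1]])
        probs = np.full((1, 4, 2), 0.5)
        edges = boundary_map(labels)
        lo = segmentation_loss(probs, labels, LossConfig(np.ones(2), edge_boost=2.0),
                               edge_mask=edges)
        hi = segmentation_loss(probs, labels, LossConfig(np.ones(2), edge_boost=4.0),
                               edge_mask=edges)
        assert hi > lo

    def test_unnormalized_probs_rejected(self):
        probs = np.full((2, 2, 2), 0.4)
        with pytest.raises(ContractViolationError):
            segmentation_loss(probs, np.zeros((2, 2), int), LossConfig(np.ones(2)))

    def test_matches_direct_recomputation(self, rng):
        # independent oracle: explicit python loops over voxels/classes
        s = 3
        labels = rng.integers(0, s, (4, 5))
        logits = rng.standard_normal((4, 5, s))
        probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
        edges = boundary_map(labels)
        w = np.array([0.5, 1.0, 2.0])
        cfg = LossConfig(w, edge_boost=3.0, dice_weight=0.7)
        ce = 0.0
        for i in range(4):
            for j in range(5):
                t = labels[i, j]
                wt = w[t] * (3.0 if edges[i, j] else 1.0)
                ce += wt * -np.log(probs[i, j, t])
        ce /= 20
        dice = 0.0
        for c in range(s):
            p_c = probs[..., c].sum()
            t_c = (labels == c).sum()
            i_c = probs[..., c][labels == c].sum()
            dice += 1 - (2 * i_c + 1e-6) / (p_c + t_c + 1e-6)
        dice /= s
        expected = ce + 0.7 * dice
        got = segmentation_loss(probs, labels, cfg, edge_mask=edges)
        assert got == pytest.approx(expected, rel=1e-9)


class TestBoundaryMap:
    def test_face_neighbors_only(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 1, 1] = 1
        edges = boundary_map(labels)
        assert edges[1, 1, 1]
        assert edges[0, 1, 1] and edges[1, 0, 1] and edges[1, 1, 0]
        assert not edges[0, 0, 0]  # diagonal neighbor: not an edge

    def test_uniform_volume_no_edges(self):
        assert not boundary_map(np.ones((4, 4, 4), int)).any()


class TestEmbedVolume:
    def test_dense_oracle_all_true_mask(self, codec):
        scheme = default_scheme(6, n_b0=1, seed=0)
        rng = np.random.default_rng(0)
        shape = (5, 4, 3)
        data = rng.uniform(0.1, 1.0, shape + (scheme.M,))
        b0 = rng.uniform(0.5, 1.5, shape)
        dwi = DWIVolume(data=data, scheme=scheme, mean_b0=b0)
        mask = np.ones(shape, bool)
        subset = scheme.dw_indices
        emb = embed_volume(dwi, mask, codec, subset)
        # dense oracle: voxel-by-voxel single encoding
        for vox in [(0, 0, 0), (2, 3, 1), (4, 1, 2)]:
            sig = np.clip(data[vox][subset] / b0[vox], 0, codec.config.clip_max)
            obs = ObservationSet(scheme.bvecs[subset], scheme.bvals[subset], sig)
            np.testing.assert_allclose(emb[vox], encode(obs, codec).values,
                                       rtol=1e-6, atol=1e-6)

    def test_out_of_mask_zero(self, codec):
        scheme = default_scheme(6, n_b0=1, seed=0)
        shape = (4, 4, 4)
        dwi = DWIVolume(data=np.ones(shape + (scheme.M,)), scheme=scheme,
                        mean_b0=np.ones(shape))
        mask = np.zeros(shape, bool)
        mask[1, 1, 1] = True
        emb = embed_volume(dwi, mask, codec, scheme.dw_indices)
        assert np.all(emb[~mask] == 0)
        assert np.any(emb[1, 1, 1] != 0)

    def test_empty_mask_no_encoder_call(self, codec, monkeypatch):
        scheme = default_scheme(6, n_b0=1, seed=0)
        shape = (4, 4, 4)
        dwi = DWIVolume(data=np.ones(shape + (scheme.M,)), scheme=scheme,
                        mean_b0=np.ones(shape))

        def boom(*a, **k):  # pragma: no cover
            raise AssertionError("encoder must not run on an empty mask")

        monkeypatch.setattr(codec, "encode_forward", boom)
        emb = embed_volume(dwi, np.zeros(shape, bool), codec, scheme.dw_indices)
        assert np.all(emb == 0)

    def test_shape_mismatch(self, codec):
        scheme = default_scheme(6, n_b0=1, seed=0)
        dwi = DWIVolume(data=np.ones((4, 4, 4, scheme.M)), scheme=scheme,
                        mean_b0=np.ones((4, 4, 4)))
        with pytest.raises(ShapeError):
            embed_volume(dwi, np.ones((5, 4, 4), bool), codec, scheme.dw_indices)

    def test_permutation_of_measurements(self, codec):
        # shuffling DWIs together with the gradient-table columns leaves
        # the embedding unchanged up to float summation order
        scheme = default_scheme(8, n_b0=1, seed=1)
        rng = np.random.default_rng(2)
        shape = (6, 6, 6)
        data = rng.uniform(0.1, 1.0, shape + (scheme.M,))
        b0 = np.ones(shape)
        mask = np.ones(shape, bool)
        perm = rng.permutation(scheme.M)
        from qseg.qspace import AcquisitionScheme
        scheme_p = AcquisitionScheme(scheme.bvecs[perm], scheme.bvals[perm])
        dwi = DWIVolume(data=data, scheme=scheme, mean_b0=b0)
        dwi_p = DWIVolume(data=data[..., perm], scheme=scheme_p, mean_b0=b0)
        inv = np.argsort(perm)
        a = embed_volume(dwi, mask, codec, scheme.dw_indices)
        b = embed_volume(dwi_p, mask, codec, inv[scheme.dw_indices])
        np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-6)


class TestAssembleSliceInput:
    @pytest.fixture()
    def volumes(self, rng):
        emb = rng.standard_normal((6, 7, 8, 4)).astype(np.float32)
        b0 = rng.standard_normal((6, 7, 8)).astype(np.float32)
        return emb, b0

    def test_channel_count(self, volumes):
        emb, b0 = volumes
        out = assemble_slice_input(emb, b0, 3, "axial")
        assert out.shape == (6, 7, 4 + 3)

    def test_channel_count_l32(self, rng):
        emb = rng.standard_normal((4, 4, 4, 32)).astype(np.float32)
        b0 = np.zeros((4, 4, 4), np.float32)
        assert assemble_slice_input(emb, b0, 1, "coronal").shape[-1] == 35

    def test_edge_replication(self, volumes):
        emb, b0 = volumes
        out = assemble_slice_input(emb, b0, 0, "axial")
        # neighbor at index-1 replicates the slice at index 0
        np.testing.assert_array_equal(out[..., 4], b0[:, :, 0])
        np.testing.assert_array_equal(out[..., 5], b0[:, :, 0])
        np.testing.assert_array_equal(out[..., 6], b0[:, :, 1])

    def test_embedding_neighbors_not_included(self, volumes):
        emb, b0 = volumes
        out = assemble_slice_input(emb, b0, 2, "sagittal")
        # only the central embedding slice is present
        np.testing.assert_array_equal(out[..., :4], emb[2])
        assert out.shape[-1] == 7

    def test_views_slice_correct_axis(self, volumes):
        emb, b0 = volumes
        assert assemble_slice_input(emb, b0, 0, "sagittal").shape == (7, 8, 7)
        assert assemble_slice_input(emb, b0, 0, "coronal").shape == (6, 8, 7)
        assert assemble_slice_input(emb, b0, 0, "axial").shape == (6, 7, 7)

    def test_invalid_view(self, volumes):
        emb, b0 = volumes
        with pytest.raises(InvalidArgumentError):
            assemble_slice_input(emb, b0, 0, "oblique")


class TestSegNet2D:
    def test_forward_shape(self):
        net = SegNet2D(in_ch=7, n_classes=3, base_width=4, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 16, 16, 7)).astype(np.float32)
        assert net.forward(x).shape == (2, 16, 16, 3)

    def test_scale_one_bitwise_neutral(self):
        net = SegNet2D(in_ch=5, n_classes=2, base_width=4, seed=1)
        x = np.random.default_rng(1).standard_normal((1, 16, 16, 5)).astype(np.float32)
        a = net.forward(x, scale=1.0)
        b = net.forward(x, scale=1.0)
        np.testing.assert_array_equal(a, b)

    def test_scaled_forward_differs_but_same_shape(self):
        net = SegNet2D(in_ch=5, n_classes=2, base_width=4, seed=1)
        x = np.random.default_rng(1).standard_normal((1, 16, 16, 5)).astype(np.float32)
        y = net.forward(x, scale=1.2)
        assert y.shape == (1, 16, 16, 2)
        assert not np.array_equal(y, net.forward(x, scale=1.0))

    def test_checkpoint_round_trip(self, tmp_path):
        net = SegNet2D(in_ch=6, n_classes=4, base_width=4, seed=2)
        save_segnet(tmp_path / "net.npz", net)
        back = load_segnet(tmp_path / "net.npz")
        x = np.random.default_rng(0).standard_normal((1, 8, 8, 6)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))


class _FakeNet:
    """Duck-typed view network emitting constant class probabilities."""

    def __init__(self, probs):
        self._logits = np.log(np.asarray(probs, dtype=np.float32))
        self.n_classes = len(probs)

    def forward(self, x, scale=1.0):
        b, h, w, _ = x.shape
        return np.broadcast_to(self._logits, (b, h, w, self.n_classes)).copy()


class TestPredictSegmentation:
    @pytest.fixture()
    def toy_dwi(self):
        scheme = default_scheme(6, n_b0=1, seed=0)
        shape = (8, 8, 8)
        return DWIVolume(data=np.full(shape + (scheme.M,), 0.5),
                         scheme=scheme, mean_b0=np.ones(shape))

    def test_hand_computed_view_mean(self, toy_dwi, codec):
        # (0.6,0.4) / (0.4,0.6) / (0.4,0.6) -> mean (0.467, 0.533) -> class 1
        nets = {
            "axial": _FakeNet([0.6, 0.4]),
            "coronal": _FakeNet([0.4, 0.6]),
            "sagittal": _FakeNet([0.4, 0.6]),
        }
        mask = np.ones((8, 8, 8), bool)
        seg, probs = predict_segmentation(
            toy_dwi, mask, nets, codec, toy_dwi.scheme.dw_indices, return_probs=True)
        np.testing.assert_allclose(probs[0, 0, 0], [1.4 / 3, 1.6 / 3], rtol=1e-5)
        assert np.all(seg.labels == 1)

    def test_identical_views_equal_single_view(self, toy_dwi, codec):
        mask = np.ones((8, 8, 8), bool)
        three = {v: _FakeNet([0.2, 0.5, 0.3]) for v in ("axial", "coronal", "sagittal")}
        one = {"axial": _FakeNet([0.2, 0.5, 0.3])}
        a = predict_segmentation(toy_dwi, mask, three, codec, toy_dwi.scheme.dw_indices)
        b = predict_segmentation(toy_dwi, mask, one, codec, toy_dwi.scheme.dw_indices)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_out_of_mask_forced_background(self, toy_dwi, codec):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        nets = {"axial": _FakeNet([0.1, 0.9])}
        seg = predict_segmentation(toy_dwi, mask, nets, codec, toy_dwi.scheme.dw_indices)
        assert np.all(seg.labels[~mask] == 0)
        assert np.all(seg.labels[mask] == 1)

    def test_no_views_rejected(self, toy_dwi, codec):
        with pytest.raises(InvalidArgumentError):
            predict_segmentation(toy_dwi, np.ones((8, 8, 8), bool), {}, codec,
                                 toy_dwi.scheme.dw_indices)

    def test_argmax_tie_breaks_low_index(self, toy_dwi, codec):
        nets = {"axial": _FakeNet([0.5, 0.5])}
        seg = predict_segmentation(toy_dwi, np.ones((8, 8, 8), bool), nets, codec,
                                   toy_dwi.scheme.dw_indices)
        assert np.all(seg.labels == 0)


@pytest.fixture(scope="module")
def prepared(tiny_setup, codec):
    scheme, phantom, dwi = tiny_setup
    vol = prepare_training_volume(dwi, phantom.mask, phantom.labels, codec.config)
    return scheme, [vol]


class TestTrainView:
    def _config(self, **kw):
        base = dict(steps=25, batch_slices=2, lr=3e-3, base_width=4,
                    scale_augment=True)
        base.update(kw)
        return SegTrainConfig(**base)

    def test_frozen_encoder_bit_identical(self, prepared, codec):
        scheme, vols = prepared
        digest = codec.param_digest()
        net, history = train_view("coronal", vols, TrainScheme.PRETRAIN_FROZEN,
                                  codec, scheme, self._config(), seed=0)
        assert codec.param_digest() == digest
        assert len(history["seg_loss"]) == 25
        assert np.all(np.isfinite(history["seg_loss"]))

    def test_frozen_reproducible_history(self, prepared, codec):
        scheme, vols = prepared
        _, h1 = train_view("axial", vols, TrainScheme.PRETRAIN_FROZEN, codec,
                           scheme, self._config(steps=8), seed=3)
        _, h2 = train_view("axial", vols, TrainScheme.PRETRAIN_FROZEN, codec,
                           scheme, self._config(steps=8), seed=3)
        assert h1["seg_loss"] == h2["seg_loss"]

    def test_scratch_updates_encoder_and_learns(self, prepared):
        scheme, vols = prepared
        enc = SetCodec(EncoderConfig(L=4, hidden_width=8, pre_depth=2, dec_depth=2),
                       seed=9)
        digest = enc.param_digest()
        _, history = train_view("coronal", vols, TrainScheme.SCRATCH_SEG_ONLY,
                                enc, scheme, self._config(steps=60), seed=1)
        assert enc.param_digest() != digest
        first = np.mean(history["seg_loss"][:10])
        last = np.mean(history["seg_loss"][-10:])
        assert last < first

    def test_multitask_records_both_histories(self, prepared):
        scheme, vols = prepared
        enc = SetCodec(EncoderConfig(L=4, hidden_width=8, pre_depth=2, dec_depth=2),
                       seed=10)
        dec_digest_before = enc.param_digest()
        _, history = train_view("axial", vols, TrainScheme.MULTITASK_SEG_RECON,
                                enc, scheme, self._config(steps=15), seed=2)
        assert len(history["recon_loss"]) == 15
        assert np.all(np.isfinite(history["recon_loss"]))
        assert np.all(np.isfinite(history["seg_loss"]))
        assert enc.param_digest() != dec_digest_before

    def test_missing_encoder_rejected(self, prepared):
        scheme, vols = prepared
        with pytest.raises(ConfigurationError):
            train_view("axial", vols, TrainScheme.PRETRAIN_FROZEN, None, scheme,
                       self._config(), seed=0)

    def test_unknown_view(self, prepared, codec):
        scheme, vols = prepared
        with pytest.raises(InvalidArgumentError):
            train_view("oblique", vols, TrainScheme.PRETRAIN_FROZEN, codec,
                       scheme, self._config(), seed=0)
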