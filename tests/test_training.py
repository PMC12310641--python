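"""Training pipeline: augmentation laws, loss properties, inference cleanup."""
import numpy as np
import pytest

from lidcurve.network import NetConfig, build_network
from lidcurve.nn.autograd import Tensor
from lidcurve.synth import rasterize_masks, render_photograph, sample_eye_geometry
from lidcurve.training import (TrainConfig, augment_pair, clean_mask,
                               compound_loss, fit_network, infer_masks,
                               load_checkpoint, prepare_sample, save_checkpoint)


def small_sample(seed=0, size=(64, 96)):
    g = sample_eye_geometry(seed, height=128, width=192)
    fis, cor = rasterize_masks(g)
    img = render_photograph(g, (fis, cor), seed)
    return prepare_sample(img, fis, cor, size)


# -- augmentation ------------------------------------------------------

def test_augment_identity_when_disabled():
    img, fis, cor = small_sample()
    tc = TrainConfig(augment_crop=False, augment_hflip=False, augment_vflip=False)
    out_img, (out_f, out_c) = augment_pair(img, (fis, cor),
                                           np.random.default_rng(0), tc)
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_f, fis) and np.array_equal(out_c, cor)


def test_horizontal_flip_applied_identically():
    """When the flip fires, image and both masks are column-reversed by the
    same transform; otherwise all three pass through unchanged."""
    img, fis, cor = small_sample()
    tc = TrainConfig(augment_crop=False, augment_vflip=False, augment_hflip=True)
    saw_flip = saw_identity = False
    for s in range(10):
        out_img, (out_f, out_c) = augment_pair(img, (fis, cor),
                                               np.random.default_rng(s), tc)
        if np.array_equal(out_f, fis[:, ::-1]) and not np.array_equal(fis, fis[:, ::-1]):
            assert np.array_equal(out_img, img[:, ::-1])
            assert np.array_equal(out_c, cor[:, ::-1])
            saw_flip = True
        else:
            assert np.array_equal(out_img, img)
            assert np.array_equal(out_f, fis) and np.array_equal(out_c, cor)
            saw_identity = True
    assert saw_flip and saw_identity


def test_augmentation_preserves_binarity_and_subset_law():
    img, fis, cor = small_sample()
    tc = TrainConfig()
    rng = np.random.default_rng(11)
    for _ in range(200):
        _, (f, c) = augment_pair(img, (fis, cor), rng, tc)
        assert f.dtype == bool and c.dtype == bool
        assert not (c & ~f).any()


# -- loss --------------------------------------------------------------

def test_loss_near_zero_at_perfection():
    t = (np.random.default_rng(0).random((1, 1, 8, 8)) > 0.5)
    eps = 1e-6
    p = Tensor(np.where(t, 1.0 - eps, eps).astype(np.float32))
    loss = compound_loss({"fissure": p}, {"fissure": t})
    assert 0 <= loss.item() < 1e-4


def test_loss_bce_closed_form_at_half():
    """p = 0.5 everywhere, half the targets one: BCE term is ln 2 and the
    soft-Dice term is 1 - 2*(0.5*n/2)/(0.5*n + n/2) = 1/2."""
    t = np.zeros((1, 1, 4, 4), bool)
    t[0, 0, :2] = True
    p = Tensor(np.full((1, 1, 4, 4), 0.5, np.float32))
    loss = compound_loss({"cornea": p}, {"cornea": t})
    assert loss.item() == pytest.approx(np.log(2) + 0.5, abs=1e-5)


def test_loss_positive_unless_match_and_swap_increases():
    rng = np.random.default_rng(1)
    t_a = rng.random((1, 1, 6, 6)) > 0.3
    t_b = rng.random((1, 1, 6, 6)) > 0.8
    p_a = Tensor(np.where(t_a, 0.95, 0.05).astype(np.float32))
    p_b = Tensor(np.where(t_b, 0.95, 0.05).astype(np.float32))
    matched = compound_loss({"fissure": p_a, "cornea": p_b},
                            {"fissure": t_a, "cornea": t_b}).item()
    swapped = compound_loss({"fissure": p_b, "cornea": p_a},
                            {"fissure": t_a, "cornea": t_b}).item()
    assert matched > 0
    assert swapped > matched


def test_loss_shape_mismatch_raises():
    p = Tensor(np.full((1, 1, 4, 4), 0.5, np.float32))
    with pytest.raises(ValueError):
        compound_loss({"fissure": p}, {"fissure": np.zeros((1, 1, 5, 5), bool)})


def test_loss_pixel_permutation_invariance():
    rng = np.random.default_rng(2)
    t = rng.random(64) > 0.5
    p = rng.random(64).astype(np.float32) * 0.9 + 0.05
    perm = rng.permutation(64)
    l1 = compound_loss({"fissure": Tensor(p.reshape(1, 1, 8, 8))},
                       {"fissure": t.reshape(1, 1, 8, 8)}).item()
    l2 = compound_loss({"fissure": Tensor(p[perm].reshape(1, 1, 8, 8))},
                       {"fissure": t[perm].reshape(1, 1, 8, 8)}).item()
    assert l1 == pytest.approx(l2, rel=1e-5)


# -- inference post-processing ----------------------------------------

def test_largest_component_survives():
    m = np.zeros((20, 20), bool)
    m[2:12, 2:12] = True       # 100 px blob
    m[15:16, 15:20] = True     # 5 px blob
    cleaned = clean_mask(m)
    assert cleaned[5, 5] and not cleaned[15, 16]
    assert cleaned.sum() == 100


def test_hole_filling():
    m = np.zeros((10, 10), bool)
    m[2:8, 2:8] = True
    m[5, 5] = False
    assert clean_mask(m)[5, 5]


def test_infer_masks_empty_sentinel_warns():
    cfg = NetConfig(base_channels=8, depth=2, input_size=(32, 48))
    net = build_network(cfg, seed=0)
    # drive the heads to all-background with a strongly negative bias
    for dec in net.decoders.values():
        dec.head.bias.data[:] = -50.0
    with pytest.warns(RuntimeWarning):
        masks = infer_masks(net, np.zeros((32, 48, 3), np.float32))
    assert not masks["fissure"].any() and not masks["cornea"].any()


# -- training loop contracts ------------------------------------------

def _tiny_manifest(n=4, size=(32, 48)):
    samples = {}
    ids = []
    for i in range(n):
        img, fis, cor = small_sample(seed=i, size=size)
        sid = f"s{i}"
        samples[sid] = {"id": sid, "image": img, "fissure": fis, "cornea": cor}
        ids.append(sid)
    manifest = {"train": ids[:-1], "test": ids[-1:]}
    return manifest, samples


def test_seeding_gives_identical_first_epoch():
    manifest, samples = _tiny_manifest()
    losses = []
    for _ in range(2):
        net = build_network(NetConfig(base_channels=8, depth=2,
                                      input_size=(32, 48)), seed=0)
        _, log = fit_network(net, manifest, TrainConfig(epochs=1, seed=5),
                             preloaded=samples)
        losses.append(log[0]["train_loss"])
    assert losses[0] == losses[1]


def test_log_length_and_checkpoint_roundtrip(tmp_path):
    manifest, samples = _tiny_manifest()
    net = build_network(NetConfig(base_channels=8, depth=2,
                                  input_size=(32, 48)), seed=0)
    net, log = fit_network(net, manifest, TrainConfig(epochs=3, seed=0),
                           preloaded=samples)
    assert len(log) == 3
    ckpt = tmp_path / "model.ckpt"
    save_checkpoint(net, ckpt, log)
    net2, log2 = load_checkpoint(ckpt)
    img = samples["s0"]["image"]
    m1 = infer_masks(net, img)
    m2 = infer_masks(net2, img)
    assert np.array_equal(m1["fissure"], m2["fissure"])
    assert len(log2) == 3


def test_empty_split_raises():
    manifest, samples = _tiny_manifest()
    manifest = {"train": [], "test": manifest["test"]}
    net = build_network(NetConfig(base_channels=8, depth=2,
                                  input_size=(32, 48)), seed=0)
    with pytest.raises(ValueError):
        fit_network(net, manifest, TrainConfig(epochs=1), preloaded=samples)
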