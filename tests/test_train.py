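import numpy as np
import pytest

from forceseg.nn import ModelConfig
from forceseg.synthetic import SceneParams, generate_scene, make_dataset
from forceseg.train import (
    TrainConfig,
    augment,
    cosine_lr,
    load_checkpoint,
    load_manifest,
    save_checkpoint,
    train,
)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("tinyds")
    params = SceneParams(height=48, width=48, n_cells=2, overlap_target=0.1)
    make_dataset(12, out, params, seed=3)
    return out


def test_cosine_lr_examples():
    assert cosine_lr(0, 10, 1e-3) == pytest.approx(1e-3)
    assert cosine_lr(5, 10, 1e-3) == pytest.approx(5e-4)
    vals = [cosine_lr(e, 10, 1e-3) for e in range(10)]
    assert all(b < a for a, b in zip(vals, vals[1:]))
    assert vals[-1] > 0
    with pytest.raises(ValueError):
        cosine_lr(10, 10, 1e-3)


def test_augment_deterministic():
    scene = generate_scene(48, 48, 2, 0.0, seed=1)
    a = augment(scene.image, scene.labels, seed=9)
    b = augment(scene.image, scene.labels, seed=9)
    assert np.array_equal(a[0], b[0])
    assert np.array_equal(a[1], b[1])
    assert a[2] == b[2]


def test_augment_identity_transform():
    scene = generate_scene(48, 48, 2, 0.0, seed=1)
    img, lab, points = augment(
        scene.image, scene.labels, seed=0,
        rotation_degrees=0.0, hflip_prob=0.0, elastic_sigma=0.0,
        gamma_range=(1.0, 1.0),
    )
    assert np.array_equal(lab, scene.labels)
    assert points == scene.extreme_points
    assert np.allclose(img, scene.image.astype(float) / 255.0, atol=1e-6)


def test_augment_flip_points_revalidate():
    scene = generate_scene(48, 48, 2, 0.0, seed=2)
    _, lab, points = augment(
        scene.image, scene.labels, seed=0,
        rotation_degrees=0.0, hflip_prob=1.0, elastic_sigma=0.0,
    )
    assert np.array_equal(lab, scene.labels[:, ::-1])
    for i, ep in points.items():
        ep.validate(lab == i)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(n_epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(base_lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(ablation_mode="everything")
    cfg = TrainConfig(ablation_mode="force_only")
    assert cfg.use_force and not cfg.use_point_losses


def test_train_two_epochs_bookkeeping(tiny_dataset, tmp_path):
    cfg = TrainConfig(n_epochs=2, batch_size=4, seed=0, ablation_mode="full")
    model, hist = train(
        tiny_dataset, cfg, model_config=ModelConfig.ablation_scale(),
        out_dir=tmp_path,
    )
    assert len(hist.records) <= 2
    for rec in hist.records:
        assert rec.lr == pytest.approx(cosine_lr(rec.epoch, 2, cfg.base_lr))
    # curriculum: effective weak-loss weights are non-decreasing
    effs = [(r.eff_w_boundary, r.eff_w_point) for r in hist.records]
    assert all(b >= a for a, b in zip(effs, effs[1:]))
    assert (tmp_path / "history.csv").exists()
    assert (tmp_path / "model.npz").exists()
    assert (tmp_path / "model.json").exists()


def test_ablation_mode_none_masks_weak_losses(tiny_dataset):
    cfg = TrainConfig(n_epochs=1, batch_size=4, seed=0, ablation_mode="none")
    _, hist = train(tiny_dataset, cfg, model_config=ModelConfig.ablation_scale())
    assert hist.records[0].l_pd == 0.0
    assert hist.records[0].l_boundary == 0.0


def test_checkpoint_roundtrip(tiny_dataset, tmp_path):
    cfg = TrainConfig(n_epochs=1, batch_size=4, seed=1, ablation_mode="points_only")
    model, _ = train(tiny_dataset, cfg, model_config=ModelConfig.ablation_scale())
    save_checkpoint(model, tmp_path / "ckpt.npz")
    loaded = load_checkpoint(tmp_path / "ckpt.npz")
    from forceseg.nn import Tensor, no_grad

    x = Tensor(np.random.default_rng(0).random((1, 3, 48, 48)))
    model.eval(), loaded.eval()
    with no_grad():
        assert np.allclose(model(x).data, loaded(x).data)


def test_train_errors(tmp_path):
    cfg = TrainConfig(n_epochs=1)
    with pytest.raises(FileNotFoundError):
        train(tmp_path, cfg)
    # a single scene lands in the train split, leaving validation empty
    params = SceneParams(height=48, width=48, n_cells=2, overlap_target=0.0)
    make_dataset(1, tmp_path, params, seed=0)
    manifest = load_manifest(tmp_path)
    assert [e["split"] for e in manifest] == ["train"]
    with pytest.raises(ValueError):
        train(tmp_path, cfg)
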