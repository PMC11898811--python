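import json

import numpy as np
import pytest

from forceseg.synthetic import (
    PlacementError,
    SceneParams,
    _arbitrate,
    _ellipse_membership,
    _split_assignment,
    generate_scene,
    load_extreme_points,
    load_label_map,
    make_dataset,
)


def test_determinism():
    a = generate_scene(64, 64, 3, 0.1, seed=7)
    b = generate_scene(64, 64, 3, 0.1, seed=7)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.labels, b.labels)
    assert a.extreme_points == b.extreme_points
    c = generate_scene(64, 64, 3, 0.1, seed=8)
    assert not np.array_equal(a.image, c.image)


def test_overlap_target_example():
    scene = generate_scene(96, 96, 4, 0.25, 0.1, seed=3)
    # brute-force pixel membership over the analytic ellipses
    members = np.stack(
        [_ellipse_membership((96, 96), c) for c in scene.cells]
    )
    count = members.sum(axis=0)
    overlap = np.count_nonzero(count >= 2) / np.count_nonzero(count > 0)
    assert abs(overlap - scene.overlap_fraction) < 1e-12
    assert abs(scene.overlap_fraction - 0.25) <= 0.15


def test_arbitration_nearest_center():
    scene = generate_scene(64, 64, 4, 0.3, seed=1)
    members = np.stack(
        [_ellipse_membership((64, 64), c) for c in scene.cells]
    )
    centers = [c.center for c in scene.cells]
    rr, cc = np.nonzero(members.sum(axis=0) >= 2)
    for r, c in zip(rr, cc):
        cands = [i for i in range(len(scene.cells)) if members[i, r, c]]
        dists = [np.hypot(r - centers[i][0], c - centers[i][1]) for i in cands]
        # assigned label is the nearest candidate center (lower id on ties)
        best = min(zip(dists, cands))[1]
        assert scene.labels[r, c] == best + 1


def test_extreme_points_from_arbitrated_masks():
    scene = generate_scene(64, 64, 4, 0.3, seed=2)
    for i, ep in scene.extreme_points.items():
        ep.validate(scene.labels == i)


def test_disjoint_scenes_have_separated_instances():
    scene = generate_scene(96, 96, 3, 0.0, seed=5)
    assert scene.overlap_fraction == 0.0
    from scipy import ndimage

    _, n = ndimage.label(scene.labels > 0, structure=np.ones((3, 3), int))
    assert n == 3


def test_placement_error_when_impossible():
    with pytest.raises(PlacementError):
        generate_scene(32, 32, 30, 0.0, seed=0)


def test_split_assignment_fractions():
    splits = _split_assignment(10, seed=0)
    assert sorted(splits).count("train") == 6
    assert sorted(splits).count("val") == 2
    assert sorted(splits).count("test") == 2
    # remainder ties go to train first
    splits11 = _split_assignment(11, seed=0)
    assert splits11.count("train") == 7


def test_make_dataset_roundtrip(tmp_path):
    params = SceneParams(height=48, width=48, n_cells=2, overlap_target=0.1)
    manifest = make_dataset(5, tmp_path, params, seed=4)
    assert len(manifest) == 5
    lines = (tmp_path / "manifest.jsonl").read_text().splitlines()
    assert len(lines) == 5
    entry = json.loads(lines[0])
    labels = load_label_map(tmp_path / entry["labels"])
    points = load_extreme_points(tmp_path / entry["points"])
    assert labels.max() == entry["n_instances"]
    assert set(points) == set(range(1, labels.max() + 1))
    for i, ep in points.items():
        ep.validate(labels == i)


def test_scene_params_validation():
    with pytest.raises(ValueError):
        generate_scene(16, 64, 2)        # too small
    with pytest.raises(ValueError):
        generate_scene(64, 64, 0)        # no cells
    with pytest.raises(ValueError):
        generate_scene(64, 64, 2, overlap_target=1.0)
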