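import math

import numpy as np
import pytest

from forceseg.metrics import (
    ConfusionCounts,
    boundary_f1,
    confusion,
    evaluate_dataset,
    evaluate_pair,
    region_metrics,
)


def test_confusion_identity_and_complement():
    ones = np.ones((4, 4), dtype=bool)
    c = confusion(ones, ones)
    assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)
    c2 = confusion(ones, ~ones)
    assert c2.tp == 0 and c2.tn == 0
    with pytest.raises(ValueError):
        confusion(ones, ones[:2])


def test_confusion_matches_brute_force(rng):
    p = rng.random((16, 16)) < 0.5
    t = rng.random((16, 16)) < 0.5
    c = confusion(p, t)
    tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for r in range(16):
        for col in range(16):
            key = ("t" if p[r, col] == t[r, col] else "f") + (
                "p" if p[r, col] else "n"
            )
            tally[key] += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (
        tally["tp"], tally["fp"], tally["fn"], tally["tn"]
    )
    assert c.total == 256


def test_region_metrics_hand_example():
    # |A| = 4, |B| = 6, |A∩B| = 3
    dice, iou, precision, recall, f1 = region_metrics(ConfusionCounts(3, 1, 3, 9))
    assert dice == pytest.approx(0.6)
    assert iou == pytest.approx(3 / 7)
    assert precision == pytest.approx(3 / 4)
    assert recall == pytest.approx(3 / 6)


def test_region_metrics_degenerate_conventions():
    assert region_metrics(ConfusionCounts(0, 0, 0, 16)) == (1, 1, 1, 1, 1)
    assert region_metrics(ConfusionCounts(0, 4, 0, 12)) == (0, 0, 0, 0, 0)
    assert region_metrics(ConfusionCounts(0, 0, 4, 12)) == (0, 0, 0, 0, 0)


def test_dice_iou_identity_and_f1(rng):
    for _ in range(100):
        p = rng.random((12, 12)) < 0.5
        t = rng.random((12, 12)) < 0.5
        dice, iou, _, _, f1 = region_metrics(confusion(p, t))
        assert abs(dice - 2 * iou / (1 + iou)) < 1e-12
        assert abs(dice - f1) < 1e-12


def test_boundary_f1_identity_and_shift():
    t = np.zeros((32, 32), dtype=bool)
    t[10:20, 10:20] = True
    assert boundary_f1(t, t, tolerance=0) == 1.0
    # shifted right by 3: vertical edges are 3 px away (miss at tol 2) but
    # the horizontal edges still partially coincide, so 0 < BF < 1
    shifted = np.roll(t, 3, axis=1)
    assert 0.0 < boundary_f1(shifted, t, tolerance=2) < 1.0
    assert boundary_f1(shifted, t, tolerance=3) == 1.0
    # fully disjoint squares: no boundary pixel within tolerance
    far = np.zeros((32, 32), dtype=bool)
    far[10:20, 22:30] = True
    near = np.zeros((32, 32), dtype=bool)
    near[10:20, 2:10] = True
    assert boundary_f1(far, near, tolerance=2) == 0.0


def test_boundary_f1_monotone_in_tolerance(rng):
    p = rng.random((20, 20)) < 0.4
    t = rng.random((20, 20)) < 0.4
    vals = [boundary_f1(p, t, tol) for tol in range(6)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        boundary_f1(p, t, -1)


def test_boundary_f1_matches_brute_force(rng):
    from forceseg.losses import extract_boundary

    for _ in range(10):
        p = rng.random((14, 14)) < 0.4
        t = rng.random((14, 14)) < 0.4
        pb, tb = extract_boundary(p).points, extract_boundary(t).points
        if not pb or not tb:
            continue
        tol = 2.0

        def frac(a, b):
            return np.mean(
                [
                    min(math.hypot(x[0] - y[0], x[1] - y[1]) for y in b) <= tol
                    for x in a
                ]
            )

        bp, br = frac(pb, tb), frac(tb, pb)
        expected = 0.0 if bp + br == 0 else 2 * bp * br / (bp + br)
        assert boundary_f1(p, t, tol) == pytest.approx(expected, abs=1e-12)


def test_metrics_rotation_invariance(rng):
    p = rng.random((16, 16)) < 0.5
    t = rng.random((16, 16)) < 0.5
    a = evaluate_pair(p, t)
    b = evaluate_pair(np.rot90(p), np.rot90(t))
    for name in ("dice", "iou", "precision", "recall", "f1", "bf"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-12)


def test_evaluate_dataset_means(rng):
    t1 = np.zeros((8, 8), dtype=bool)
    t1[2:6, 2:6] = True
    p2 = np.zeros((8, 8), dtype=bool)
    p2[2:6, 2:4] = True  # half of t1 -> dice 2/3
    df = evaluate_dataset([t1, p2], [t1, t1])
    assert len(df) == 3
    mean = df[df.image_id == "mean"].iloc[0]
    per_image = df[df.image_id != "mean"]
    assert mean["dice"] == pytest.approx(per_image["dice"].mean())
    assert per_image["dice"].iloc[0] == 1.0
    with pytest.raises(ValueError):
        evaluate_dataset({"a": t1}, {"b": t1})


def test_evaluate_dataset_perfect_prediction():
    t = np.zeros((8, 8), dtype=np.int32)
    t[1:4, 1:4] = 1
    df = evaluate_dataset({"img": t}, {"img": t})
    mean = df[df.image_id == "mean"].iloc[0]
    for name in ("dice", "iou", "precision", "recall", "f1", "bf"):
        assert mean[name] == 1.0
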