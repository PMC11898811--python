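import math

import numpy as np
import pytest

from forceseg.losses import (
    LossWeights,
    boundary_alignment_loss,
    curriculum_ramp,
    differentiable_surrogates,
    extract_boundary,
    point_distance_loss,
    segmentation_consistency_loss,
    soft_boundary_map,
    total_loss,
)
from forceseg.points import extract_extreme_points


def brute_force_boundary(mask):
    m = np.asarray(mask) > 0
    h, w = m.shape
    pts = set()
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    pts.add((r, c))
                    break
    return pts


def square_mask(h, w, r0, c0, size):
    m = np.zeros((h, w), dtype=bool)
    m[r0 : r0 + size, c0 : c0 + size] = True
    return m


def test_extract_boundary_matches_brute_force(rng):
    for _ in range(50):
        m = rng.random((12, 12)) < 0.45
        assert extract_boundary(m).points == frozenset(brute_force_boundary(m))


def test_point_distance_zero_when_boundary_through_anchors():
    m = square_mask(16, 16, 4, 4, 6)
    ep = extract_extreme_points(m)
    assert point_distance_loss(ep, extract_boundary(m)) == 0.0


def test_point_distance_matches_exhaustive(rng):
    for _ in range(30):
        target = rng.random((10, 10)) < 0.4
        pred = rng.random((10, 10)) < 0.4
        if not target.any() or not pred.any():
            continue
        ep = extract_extreme_points(target)
        b = extract_boundary(pred)
        expected = 0.0
        for p in (ep.p_top, ep.p_bottom, ep.p_left, ep.p_right):
            expected += min(
                math.hypot(p[0] - q[0], p[1] - q[1]) for q in b.points
            ) if b.points else 4 * math.hypot(10, 10)
        assert point_distance_loss(ep, b) == pytest.approx(expected, abs=1e-12)


def test_point_distance_empty_boundary_sentinel():
    m = square_mask(8, 8, 2, 2, 3)
    ep = extract_extreme_points(m)
    empty = extract_boundary(np.zeros((8, 8), dtype=bool))
    assert point_distance_loss(ep, empty) == pytest.approx(4 * math.hypot(8, 8))


def test_boundary_alignment_matches_exhaustive(rng):
    for _ in range(30):
        a = rng.random((10, 10)) < 0.4
        b = rng.random((10, 10)) < 0.4
        pa, pb = extract_boundary(a), extract_boundary(b)
        if not pa.points or not pb.points:
            continue
        dists = [
            min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in pb.points)
            for p in pa.points
        ]
        assert boundary_alignment_loss(pa, pb) == pytest.approx(
            float(np.mean(dists)), abs=1e-12
        )


def test_boundary_alignment_zero_identity_and_translation_monotone():
    target = square_mask(24, 24, 8, 8, 6)
    tb = extract_boundary(target)
    assert boundary_alignment_loss(tb, tb) == 0.0
    prev = -1.0
    for shift in range(1, 6):
        pred = square_mask(24, 24, 8, 8 + shift, 6)
        val = boundary_alignment_loss(extract_boundary(pred), tb)
        assert val > prev
        prev = val


def test_seg_loss_perfect_prediction_near_zero():
    t = square_mask(16, 16, 4, 4, 8).astype(float)
    loss = segmentation_consistency_loss(t, t, lam=0.5)
    assert 0 <= loss < 1e-2


def test_seg_loss_penalizes_confident_errors():
    t = square_mask(8, 8, 2, 2, 4).astype(float)
    good = segmentation_consistency_loss(t, t)
    bad = segmentation_consistency_loss(1.0 - t, t)
    assert bad > good + 1.0
    with pytest.raises(ValueError):
        segmentation_consistency_loss(t[:4], t)


def test_curriculum_ramp_shape():
    n = 10
    vals = [curriculum_ramp(e, n) for e in range(n)]
    assert vals[0] == 0.0
    assert vals[5] == 1.0
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        curriculum_ramp(10, 10)


def test_total_loss_weighting():
    w = LossWeights()
    bd = total_loss(l_pd=2.0, l_boundary=3.0, l_seg=1.0, weights=w, epoch=5, n_epochs=10)
    # ramp = 1 at the halfway epoch
    assert bd.l_total == pytest.approx(1.0 * 1.0 + 0.5 * 3.0 + 0.3 * 2.0)
    bd0 = total_loss(l_pd=2.0, l_boundary=3.0, l_seg=1.0, weights=w, epoch=0, n_epochs=10)
    assert bd0.l_total == pytest.approx(1.0)  # boundary/point ramped to zero
    assert bd0.eff_w_boundary == 0.0


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(w_seg=-1)
    with pytest.raises(ValueError):
        LossWeights(w_seg=0, w_boundary=0, w_point=0)


def test_soft_boundary_map_hard_mask():
    m = square_mask(16, 16, 4, 4, 8).astype(float)
    yb = soft_boundary_map(m)
    interior = square_mask(16, 16, 5, 5, 6)
    assert np.allclose(yb[interior], 0.0)
    ring = m.astype(bool) & ~interior
    assert np.allclose(yb[ring], 1.0)
    assert np.allclose(yb[~m.astype(bool)], 0.0)


def test_surrogates_agree_with_discrete_on_hard_masks():
    target = square_mask(24, 24, 8, 8, 8)
    pred = square_mask(24, 24, 9, 10, 8).astype(float)
    tb = extract_boundary(target)
    ep = extract_extreme_points(target)
    l_pd_soft, l_b_soft = differentiable_surrogates(pred, tb, [ep])
    pb = extract_boundary(pred.astype(bool))
    l_b = boundary_alignment_loss(pb, tb)
    l_pd = point_distance_loss(ep, pb)
    # agreement within the 1-px boundary discretization per term
    assert abs(l_b_soft - l_b) <= 1.0
    assert abs(l_pd_soft - l_pd) <= 4.0


def test_surrogates_empty_prediction_sentinels():
    l_pd, l_b = differentiable_surrogates(
        np.zeros((12, 12)),
        extract_boundary(square_mask(12, 12, 3, 3, 4)),
        [extract_extreme_points(square_mask(12, 12, 3, 3, 4))],
    )
    diag = math.hypot(12, 12)
    assert l_b == pytest.approx(diag)
    assert l_pd == pytest.approx(4 * diag)
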