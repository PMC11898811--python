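"""Inward-directed force fields for separating touching cell instances.

Every foreground pixel p of an instance receives a 2-vector pointing from p
toward its instance centroid C:

    F_p = −α · (p − C) / ‖p − C‖        ("unit" mode, magnitude α)
    F_p = −α · (p − C)                  ("distance" mode, magnitude grows
                                         with distance from the center)

Background pixels carry the zero vector, as does any pixel within half a
pixel of its own centroid (avoiding 0/0). Channels are ordered (Δrow, Δcol)
with 0-based coordinates. At training time the field is computed from
ground-truth instance labels; at inference it is derived from a first-pass
prediction (threshold → connected components → centroids).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "CellCenter",
    "ForceField",
    "compute_centers",
    "compute_force_field",
    "force_field_from_prediction",
]

#: pixels closer than this to their centroid get the zero vector
_CENTER_RADIUS = 0.5


@dataclass(frozen=True)
class CellCenter:
    """Centroid (arithmetic mean of pixel coordinates) of one instance."""

    center: tuple[float, float]  # (row, col), continuous
    instance_id: int


@dataclass(frozen=True)
class ForceField:
    field: np.ndarray  # H×W×2, channels (Δrow, Δcol)
    alpha: float
    mode: Literal["unit", "distance"]

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.field[..., 0], self.field[..., 1])


def compute_centers(labels: np.ndarray) -> list[CellCenter]:
    """One centroid per instance id, in increasing id order."""
    lab = np.asarray(labels)
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    centers = ndimage.center_of_mass(lab > 0, lab, ids)
    return [
        CellCenter((float(r), float(c)), int(i))
        for (r, c), i in zip(np.atleast_2d(centers), ids)
    ]


def compute_force_field(
    labels: np.ndarray,
    alpha: float = 1.0,
    mode: Literal["unit", "distance"] = "unit",
) -> ForceField:
    """Per-pixel inward force toward each pixel's own instance centroid."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if mode not in ("unit", "distance"):
        raise ValueError(f"unknown mode {mode!r}")
    lab = np.asarray(labels)
    field = np.zeros(lab.shape + (2,), dtype=float)
    rows = np.arange(lab.shape[0], dtype=float)[:, None]
    cols = np.arange(lab.shape[1], dtype=float)[None, :]
    for cc in compute_centers(lab):
        mask = lab == cc.instance_id
        dr = rows - cc.center[0]
        dc = cols - cc.center[1]
        dist = np.hypot(dr, dc)
        active = mask & (dist > _CENTER_RADIUS)
        if mode == "unit":
            with np.errstate(invalid="ignore", divide="ignore"):
                fr = np.where(active, -alpha * dr / dist, 0.0)
                fc = np.where(active, -alpha * dc / dist, 0.0)
        else:
            fr = np.where(active, -alpha * dr, 0.0)
            fc = np.where(active, -alpha * dc, 0.0)
        field[..., 0] += np.nan_to_num(fr)
        field[..., 1] += np.nan_to_num(fc)
    return ForceField(field, float(alpha), mode)


def force_field_from_prediction(
    prob_map: np.ndarray,
    alpha: float = 1.0,
    threshold: float = 0.5,
    mode: Literal["unit", "distance"] = "unit",
) -> ForceField:
    """Inference-time field: threshold → 8-connected components → force field."""
    p = np.asarray(prob_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("prob_map must be in [0, 1]")
    fg = p >= threshold
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    return compute_force_field(labels, alpha=alpha, mode=mode) if labels.any() else ForceField(
        np.zeros(p.shape + (2,), dtype=float), float(alpha), mode
    )
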