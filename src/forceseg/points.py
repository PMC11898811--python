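"""Extreme points: the four axis-extremal pixels of a cell mask.

These four anchors (topmost, bottom-most, leftmost, rightmost pixels) are the
weak supervision signal used in place of full pixel-wise labels. Tie-breaking
is fixed so that annotation extraction is deterministic:

* top: minimum row, ties broken by minimum column
* bottom: maximum row, ties broken by maximum column
* left: minimum column, ties broken by minimum row
* right: maximum column, ties broken by maximum row
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExtremePoints", "extract_extreme_points"]


class EmptyInstanceError(ValueError):
    """Raised when extreme points are requested for an empty mask."""


@dataclass(frozen=True)
class ExtremePoints:
    p_top: tuple[int, int]
    p_bottom: tuple[int, int]
    p_left: tuple[int, int]
    p_right: tuple[int, int]

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "top": list(self.p_top),
            "bottom": list(self.p_bottom),
            "left": list(self.p_left),
            "right": list(self.p_right),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtremePoints":
        return cls(
            tuple(d["top"]), tuple(d["bottom"]), tuple(d["left"]), tuple(d["right"])
        )

    def validate(self, mask: np.ndarray) -> None:
        """Check the extreme-point invariants against an instance mask."""
        m = np.asarray(mask) > 0
        rows, cols = np.nonzero(m)
        if rows.size == 0:
            raise EmptyInstanceError("mask has no foreground pixels")
        for name, (r, c) in (
            ("top", self.p_top),
            ("bottom", self.p_bottom),
            ("left", self.p_left),
            ("right", self.p_right),
        ):
            if not m[r, c]:
                raise ValueError(f"{name} point {(r, c)} not on the mask")
        if self.p_top[0] != rows.min() or self.p_bottom[0] != rows.max():
            raise ValueError("top/bottom rows are not extremal")
        if self.p_left[1] != cols.min() or self.p_right[1] != cols.max():
            raise ValueError("left/right cols are not extremal")


def extract_extreme_points(instance_mask: np.ndarray) -> ExtremePoints:
    """Extreme points of a binary instance mask under the fixed tie rules."""
    m = np.asarray(instance_mask) > 0
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyInstanceError("cannot extract extreme points of an empty mask")
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    p_top = (int(rmin), int(cols[rows == rmin].min()))
    p_bottom = (int(rmax), int(cols[rows == rmax].max()))
    p_left = (int(rows[cols == cmin].min()), int(cmin))
    p_right = (int(rows[cols == cmax].max()), int(cmax))
    return ExtremePoints(p_top, p_bottom, p_left, p_right)
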