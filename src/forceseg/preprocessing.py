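"""Pseudo-label generation from raw images: color clustering, texture
filtering, morphological cleanup, connected components and extreme points.

The pipeline bootstraps weakly-supervised training without pixel-wise labels:

1. convert to CIELAB and k-means-cluster the pixel colors (k = 3),
2. designate foreground clusters by their distance from the image-border
   median color (the border is background-dominated in cytology fields),
3. restrict the mask to textured pixels (Gabor energy and an LBP-derived
   response above within-mask Otsu thresholds) — texture can only remove
   pixels, never add them,
4. morphological opening (3×3) then closing (5×5),
5. 8-connected components become pseudo-instances (tiny ones dropped),
   each with its four extreme points.

``preprocess_image`` composes the steps in this order, after resizing to
256×256 and applying percentile stretching plus luminance CLAHE. Texture
responses are computed on the *raw* resized grayscale: contrast enhancement
amplifies sensor noise into texture-like structure, which would defeat the
texture filter's purpose of separating structured tissue from noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure, feature, filters, morphology, transform
from sklearn.cluster import KMeans

from .points import ExtremePoints, extract_extreme_points

__all__ = [
    "ClusterMap",
    "PseudoLabelMap",
    "convert_to_lab",
    "cluster_colors",
    "extract_foreground",
    "texture_refine",
    "morphological_clean",
    "components_to_instances",
    "extract_extreme_points",
    "preprocess_image",
]

logger = logging.getLogger(__name__)

TARGET_SIZE = 256
MIN_COMPONENT_AREA = 20
_GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GABOR_WAVELENGTHS = (4.0, 8.0)
_CLAHE_CLIP = 0.02       # skimage-scale clip limit (OpenCV-convention "2.0")
_CLAHE_TILES = 8
#: minimum Otsu effectiveness (between/total variance) for a texture response
#: to be considered bimodal enough to restrict on
_OTSU_SEPARABILITY_MIN = 0.5
#: a within-mask threshold that would discard more than this fraction of the
#: mask indicates a unimodal response (it would split the cell population
#: itself, not remove leaked background) and is not applied
_MAX_REMOVAL_FRACTION = 0.25


@dataclass(frozen=True)
class ClusterMap:
    labels: np.ndarray          # H×W ints in {0..k-1}
    k: int
    centers: np.ndarray         # k × 3 LAB centers


@dataclass(frozen=True)
class PseudoLabelMap:
    labels: np.ndarray          # H×W instance map, 0 = background
    connectivity: int = 8
    provenance: str = "pseudo"

    @property
    def n_instances(self) -> int:
        return int(self.labels.max())


def convert_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (0..255) → CIELAB under D65. L is on the 0..100 scale."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    return skcolor.rgb2lab(img.astype(np.float64) / 255.0)


def cluster_colors(lab_image: np.ndarray, k: int = 3, seed: int = 0) -> ClusterMap:
    """k-means (k-means++ init, fixed seed) over per-pixel LAB colors."""
    if k < 2:
        raise ValueError("k must be >= 2")
    h, w = lab_image.shape[:2]
    pixels = lab_image.reshape(-1, 3)
    n_distinct = min(k, np.unique(pixels, axis=0).shape[0])
    km = KMeans(n_clusters=n_distinct, init="k-means++", n_init=3, random_state=seed)
    labels = km.fit_predict(pixels)
    centers = km.cluster_centers_
    if n_distinct < k:
        # degenerate image: report the populated clusters only, padded centers
        centers = np.vstack([centers] + [centers[-1:]] * (k - n_distinct))
    return ClusterMap(labels.reshape(h, w).astype(np.int32), k, centers)


def extract_foreground(clusters: ClusterMap, lab_image: np.ndarray) -> np.ndarray:
    """Foreground = clusters whose mean LAB color is far from the border color.

    The median color of the 1-px image border estimates the background; the
    cluster farthest from it (Euclidean in LAB) is foreground, as is any other
    cluster more than half that maximum distance away.
    """
    lab = np.asarray(lab_image, dtype=float)
    border = np.concatenate(
        [lab[0, :], lab[-1, :], lab[1:-1, 0], lab[1:-1, -1]], axis=0
    )
    border_median = np.median(border, axis=0)
    present = np.unique(clusters.labels)
    dists = {
        int(c): float(np.linalg.norm(clusters.centers[int(c)] - border_median))
        for c in present
    }
    dmax = max(dists.values())
    if dmax <= 1e-9:
        logger.warning("degenerate image: all clusters match the border color")
        return np.zeros(clusters.labels.shape, dtype=bool)
    fg_clusters = {c for c, d in dists.items() if d > 0.5 * dmax}
    return np.isin(clusters.labels, sorted(fg_clusters))


def _gabor_energy(gray: np.ndarray) -> np.ndarray:
    """Bank energy: filter magnitudes smoothed regionally (3× each
    wavelength), so structured regions carry energy throughout rather than
    only on their edges."""
    energy = np.zeros_like(gray, dtype=float)
    for wavelength in _GABOR_WAVELENGTHS:
        for theta in _GABOR_THETAS:
            real, imag = filters.gabor(gray, frequency=1.0 / wavelength, theta=theta)
            energy += ndimage.gaussian_filter(np.hypot(real, imag), sigma=3 * wavelength)
    return energy


def _lbp_response(gray: np.ndarray) -> np.ndarray:
    """Regional fraction of uniform LBP patterns (radius 1, 8 points).

    Structured cellular texture produces mostly uniform patterns, whereas
    sensor noise yields non-uniform codes, so a high response marks
    tissue-like texture."""
    g8 = (np.asarray(gray, dtype=float) * 255).astype(np.uint8)
    codes = feature.local_binary_pattern(g8, P=8, R=1, method="uniform")
    uniform = (codes < 9).astype(float)
    return ndimage.gaussian_filter(uniform, sigma=12)


def texture_refine(mask: np.ndarray, gray: np.ndarray) -> np.ndarray:
    """Keep only mask pixels whose Gabor energy and LBP response both exceed
    Otsu thresholds computed within the current mask. Never adds pixels."""
    m = np.asarray(mask) > 0
    if not m.any():
        return m
    g = np.asarray(gray, dtype=float)
    energy = _gabor_energy(g)
    lbp = _lbp_response(g)
    keep = m.copy()
    for resp in (energy, lbp):
        vals = resp[m]
        if np.ptp(vals) <= 1e-12:
            continue  # flat response carries no information to restrict on
        thr = filters.threshold_otsu(vals)
        if _otsu_separability(vals, thr) < _OTSU_SEPARABILITY_MIN:
            continue  # not bimodal: nothing background-like to strip
        if np.mean(vals <= thr) > _MAX_REMOVAL_FRACTION:
            # the threshold would split the cell population itself rather
            # than remove leaked background; treat as unimodal
            continue
        keep &= resp > thr
    return keep


def _otsu_separability(vals: np.ndarray, thr: float) -> float:
    """Otsu's effectiveness measure η: between-class over total variance."""
    lo = vals[vals <= thr]
    hi = vals[vals > thr]
    total = vals.var()
    if lo.size == 0 or hi.size == 0 or total <= 0:
        return 0.0
    w0 = lo.size / vals.size
    w1 = 1.0 - w0
    return float(w0 * w1 * (lo.mean() - hi.mean()) ** 2 / total)


def morphological_clean(mask: np.ndarray) -> np.ndarray:
    """Opening with a 3×3 square, then closing with a 5×5 square."""
    m = np.asarray(mask) > 0
    opened = morphology.opening(m, morphology.footprint_rectangle((3, 3)))
    return morphology.closing(opened, morphology.footprint_rectangle((5, 5)))


def components_to_instances(
    mask: np.ndarray, min_area: int = MIN_COMPONENT_AREA
) -> PseudoLabelMap:
    """8-connected components, small ones dropped, ids ordered by the
    row-major position of each component's top-left-most pixel."""
    m = np.asarray(mask) > 0
    raw, n = ndimage.label(m, structure=np.ones((3, 3), int))
    keep = []
    for i in range(1, n + 1):
        comp = raw == i
        if comp.sum() >= min_area:
            rr, cc = np.nonzero(comp)
            first = (rr[0], cc[rr == rr[0]].min())  # row-major first pixel
            keep.append((first, i))
    keep.sort()
    out = np.zeros_like(raw, dtype=np.int32)
    for new_id, (_, old_id) in enumerate(keep, start=1):
        out[raw == old_id] = new_id
    return PseudoLabelMap(out)


def _normalize_contrast(image: np.ndarray) -> np.ndarray:
    """Histogram normalization + contrast enhancement.

    Per-channel percentile stretching (2–98%) standardizes staining intensity
    while preserving the hue relations the color clustering depends on; CLAHE
    is then applied to the luminance channel only.
    """
    img = np.asarray(image, dtype=np.float64) / 255.0
    stretched = np.stack(
        [
            exposure.rescale_intensity(
                img[..., c], in_range=tuple(np.percentile(img[..., c], (2, 98)))
            )
            for c in range(3)
        ],
        axis=-1,
    )
    h, w = stretched.shape[:2]
    kernel = (max(1, h // _CLAHE_TILES), max(1, w // _CLAHE_TILES))
    lab = skcolor.rgb2lab(stretched)
    l_eq = exposure.equalize_adapthist(
        lab[..., 0] / 100.0, kernel_size=kernel, clip_limit=_CLAHE_CLIP
    )
    lab[..., 0] = l_eq * 100.0
    out = np.clip(skcolor.lab2rgb(lab), 0, 1)
    return (out * 255.0).astype(np.uint8)


def preprocess_image(
    image: np.ndarray,
    k: int = 3,
    seed: int = 0,
    target_size: int = TARGET_SIZE,
    min_area: int = MIN_COMPONENT_AREA,
) -> tuple[PseudoLabelMap, dict[int, ExtremePoints]]:
    """Full pseudo-label pipeline for one RGB image.

    Resizes to `target_size` (bilinear), normalizes contrast, then runs
    clustering → foreground extraction → texture restriction → morphology →
    connected components → extreme-point extraction.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    if img.shape[:2] != (target_size, target_size):
        img = transform.resize(
            img, (target_size, target_size), order=1, preserve_range=True,
            anti_aliasing=True,
        ).astype(np.uint8)
    # texture is judged on the raw resized grayscale: CLAHE amplifies sensor
    # noise into structure, which would invert the texture responses
    raw_gray = skcolor.rgb2gray(img.astype(np.float64) / 255.0)
    img = _normalize_contrast(img)
    lab = convert_to_lab(img)
    clusters = cluster_colors(lab, k=k, seed=seed)
    fg = extract_foreground(clusters, lab)
    fg = texture_refine(fg, raw_gray)
    fg = morphological_clean(fg)
    pseudo = components_to_instances(fg, min_area=min_area)
    points = {
        i: extract_extreme_points(pseudo.labels == i)
        for i in range(1, pseudo.n_instances + 1)
    }
    return pseudo, points
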