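"""Training loop, augmentation, cosine schedule and the ablation harness.

The loop implements the weakly-supervised recipe end to end: each batch is
augmented (rotation, horizontal flip, elastic deformation, gamma jitter),
ground-truth-derived force channels are supplied to the network (teacher
forcing; inference uses the two-pass scheme in :func:`forceseg.nn.segment`),
and the loss combines the segmentation-consistency term with differentiable
surrogates of the boundary-alignment and point-distance losses under the
curriculum ramp. Adam with cosine-annealed learning rate and early stopping
on validation loss complete the recipe.

Ablation modes gate the two weak-supervision mechanisms independently:

================  ==============  ==========================
mode              force channels  boundary/point loss terms
================  ==============  ==========================
``none``          off             off
``force_only``    on              off
``points_only``   off             on
``full``          on              on
================  ==============  ==========================

``run_ablation`` trains one model per mode on shared data and seeds and
reports mean test-split Dice and Boundary-F1 per mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

from .force_map import compute_force_field
from .losses import (
    LossBreakdown,
    LossWeights,
    _SOFTMIN_T,
    boundary_alignment_loss,
    curriculum_ramp,
    extract_boundary,
    point_distance_loss,
    segmentation_consistency_loss,
)
from .metrics import evaluate_pair
from .nn import ModelConfig, SegmentationModel, Tensor, build_model, no_grad, segment
from .nn.optim import Adam
from .points import ExtremePoints, extract_extreme_points
from .synthetic import load_extreme_points, load_label_map

try:  # imageio is a hard dependency of the package; guard only for clarity
    import imageio.v2 as imageio
except ImportError:  # pragma: no cover
    import imageio

__all__ = [
    "ABLATION_MODES",
    "TrainConfig",
    "EpochRecord",
    "TrainingHistory",
    "augment",
    "cosine_lr",
    "ensure_pseudo_labels",
    "load_manifest",
    "train",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATION_MODES = ("none", "force_only", "points_only", "full")

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Epoch count and batch size default to 100/8; the optimizer follows the
    recipe exactly (Adam, LR 0.001, weight decay 1e-5, cosine annealing,
    early stopping on validation loss).
    """

    n_epochs: int = 100
    batch_size: int = 8
    base_lr: float = 1e-3
    weight_decay: float = 1e-5
    rotation_degrees: float = 15.0
    hflip_prob: float = 0.5
    elastic_grid: int = 4
    elastic_sigma: float = 3.0
    gamma_range: tuple[float, float] = (0.8, 1.2)
    scale_jitter: float = 0.0          # optional ±fraction rescale, off by default
    patience: int = 10
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    ablation_mode: str = "full"
    supervision: str = "pseudo"        # dense-target source: pseudo | ground_truth
    force_alpha: float = 1.0
    threshold: float = 0.5
    bf_tolerance: float = 2.0

    def __post_init__(self):
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("n_epochs and batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"ablation_mode must be one of {ABLATION_MODES}")
        if self.supervision not in ("pseudo", "ground_truth"):
            raise ValueError("supervision must be 'pseudo' or 'ground_truth'")

    @property
    def use_force(self) -> bool:
        return self.ablation_mode in ("force_only", "full")

    @property
    def use_point_losses(self) -> bool:
        return self.ablation_mode in ("points_only", "full")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    lr: float
    l_pd: float
    l_boundary: float
    l_seg: float
    l_total: float
    eff_w_boundary: float
    eff_w_point: float
    val_loss: float
    val_dice: float
    val_bf: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        df["best_epoch"] = self.best_epoch
        df["stopped_early"] = self.stopped_early
        return df

    def save_csv(self, path: Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _elastic_field(
    rng: np.random.Generator, shape: tuple[int, int], grid: int, sigma: float
) -> np.ndarray:
    """Dense (2,H,W) displacement field from a coarse control grid."""
    coarse = rng.normal(0.0, sigma, (2, grid, grid))
    return np.stack(
        [
            sktransform.resize(
                coarse[i], shape, order=3, mode="reflect", anti_aliasing=False
            )
            for i in range(2)
        ]
    )


def _augment_joint(
    image: np.ndarray,
    label_maps: Sequence[np.ndarray],
    seed,
    rotation_degrees: float = 15.0,
    hflip_prob: float = 0.5,
    elastic_grid: int = 4,
    elastic_sigma: float = 3.0,
    gamma_range: tuple[float, float] = (0.8, 1.2),
    scale_jitter: float = 0.0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply one randomly drawn transform to an image and several label maps."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    labs = [np.asarray(l) for l in label_maps]
    h, w = labs[0].shape

    angle = rng.uniform(-rotation_degrees, rotation_degrees)
    do_flip = rng.random() < hflip_prob
    disp = (
        _elastic_field(rng, (h, w), elastic_grid, elastic_sigma)
        if elastic_sigma > 0
        else None
    )
    gamma = rng.uniform(*gamma_range)
    scale = 1.0 + rng.uniform(-scale_jitter, scale_jitter) if scale_jitter > 0 else 1.0

    def warp_labels(fn):
        return [fn(l) for l in labs]

    if angle != 0.0:
        img = sktransform.rotate(img, angle, order=3, mode="edge", preserve_range=True)
        labs = warp_labels(
            lambda l: sktransform.rotate(
                l.astype(float), angle, order=0, mode="constant", cval=0.0,
                preserve_range=True,
            ).astype(l.dtype)
        )
    if do_flip:
        img = img[:, ::-1].copy()
        labs = warp_labels(lambda l: l[:, ::-1].copy())
    if scale != 1.0:
        # rescale about the image center, then crop/pad back to (h, w)
        mat = sktransform.AffineTransform(scale=1.0 / scale)
        shift = sktransform.AffineTransform(translation=(w / 2, h / 2))
        tform = (shift + mat + shift.inverse).inverse
        img = sktransform.warp(img, tform, order=3, mode="edge", preserve_range=True)
        labs = warp_labels(
            lambda l: sktransform.warp(
                l.astype(float), tform, order=0, mode="constant", cval=0.0,
                preserve_range=True,
            ).astype(l.dtype)
        )
    if disp is not None:
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rows + disp[0], cols + disp[1]])
        img = np.stack(
            [
                ndimage.map_coordinates(img[..., c], coords, order=3, mode="reflect")
                for c in range(img.shape[2])
            ],
            axis=-1,
        )
        labs = warp_labels(
            lambda l: ndimage.map_coordinates(l, coords, order=0, mode="constant", cval=0)
        )

    img = np.clip(img, 0.0, 1.0) ** gamma
    return img, labs


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    seed,
    rotation_degrees: float = 15.0,
    hflip_prob: float = 0.5,
    elastic_grid: int = 4,
    elastic_sigma: float = 3.0,
    gamma_range: tuple[float, float] = (0.8, 1.2),
    scale_jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict[int, ExtremePoints]]:
    """Jointly augment an image and its instance label map.

    The same geometric transform (rotation ~ U(±rotation_degrees), horizontal
    flip with probability `hflip_prob`, elastic deformation from a
    `elastic_grid`² control grid with displacement σ = `elastic_sigma` px,
    optional ±`scale_jitter` rescale) is applied to both; the image is
    interpolated bicubically, labels nearest-neighbour. Contrast jitter is a
    random gamma in `gamma_range` on the image only. Extreme points are
    recomputed from the transformed label map — never transformed as
    coordinates — so they always satisfy their invariants on the output mask.
    Returns the image as float in [0,1].
    """
    img, (lab,) = _augment_joint(
        image, [labels], seed, rotation_degrees, hflip_prob, elastic_grid,
        elastic_sigma, gamma_range, scale_jitter,
    )
    points: dict[int, ExtremePoints] = {}
    for i in np.unique(lab):
        if i > 0:
            points[int(i)] = extract_extreme_points(lab == i)
    return img, lab, points


def cosine_lr(epoch: int, n_epochs: int, base_lr: float) -> float:
    """Cosine annealing: base_lr × ½(1 + cos(π·epoch/n_epochs)), floored at 0."""
    if not (0 <= epoch < n_epochs):
        raise ValueError("epoch must satisfy 0 <= epoch < n_epochs")
    return max(0.0, base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / n_epochs)))


# ---------------------------------------------------------------------------
# Dataset plumbing
# ---------------------------------------------------------------------------


def load_manifest(dataset_dir: Path) -> list[dict]:
    """Read manifest.jsonl written by :func:`forceseg.synthetic.make_dataset`."""
    path = Path(dataset_dir) / "manifest.jsonl"
    entries = [json.loads(line) for line in path.read_text().splitlines() if line]
    if not entries:
        raise ValueError(f"empty manifest: {path}")
    return entries


def _load_sample(dataset_dir: Path, entry: dict):
    d = Path(dataset_dir)
    image = np.asarray(imageio.imread(d / entry["image"]))
    labels = load_label_map(d / entry["labels"])
    points = load_extreme_points(d / entry["points"])
    return image, labels, points


def ensure_pseudo_labels(
    dataset_dir: Path, entries: Sequence[dict], seed: int = 0
) -> None:
    """Generate (and cache) pseudo-label maps for the given manifest entries.

    Runs :func:`forceseg.preprocessing.preprocess_image` once per scene and
    stores the result, downsampled (nearest) to the scene's native resolution,
    as ``<image-stem>_pseudo.png`` next to the scene files. Existing files are
    reused, so repeated training runs pay the preprocessing cost only once.
    """
    from skimage import transform as _tf

    from .preprocessing import preprocess_image

    d = Path(dataset_dir)
    for entry in entries:
        out = d / (Path(entry["image"]).stem + "_pseudo.png")
        if out.exists():
            continue
        image = np.asarray(imageio.imread(d / entry["image"]))
        pseudo, _ = preprocess_image(image, seed=seed)
        native = _tf.resize(
            pseudo.labels, image.shape[:2], order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(np.uint16)
        imageio.imwrite(out, native)


def _load_pseudo(dataset_dir: Path, entry: dict) -> np.ndarray:
    path = Path(dataset_dir) / (Path(entry["image"]).stem + "_pseudo.png")
    return np.asarray(imageio.imread(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# Differentiable batch loss
# ---------------------------------------------------------------------------


def _sample_seg_loss(p: Tensor, truth: np.ndarray, lam: float) -> Tensor:
    t = truth.astype(p.data.dtype)
    pc = p.clip(_EPS, 1.0 - _EPS)
    bce = -(Tensor(t) * pc.log() + Tensor(1.0 - t) * (1.0 - pc).log()).mean()
    inter = (p * Tensor(t)).sum()
    dice = (2.0 * inter + 1.0) / (p.sum() + float(t.sum()) + 1.0)
    return bce + lam * (1.0 - dice)


def _sample_weak_losses(
    p: Tensor,
    d_target: np.ndarray,
    point_kernels: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[Tensor, Tensor]:
    """Soft (l_pd, l_boundary) surrogates as autograd graph nodes.

    `d_target` is the (constant) distance transform of the target boundary;
    `point_kernels` holds, per extreme point, its distance map D and the Gibbs
    weight map exp(−D/T). The soft boundary map ŷ − minpool₃(ŷ) localizes the
    prediction's contour; both losses are its weighted means, so gradients
    flow only through sums and divisions.
    """
    h, w = p.shape[-2:]
    diag = math.hypot(h, w)
    yb = (p.reshape(1, 1, h, w) - p.reshape(1, 1, h, w).minpool3()).reshape(h, w)
    mass = yb.sum()
    if float(mass.data) <= _EPS:
        # no predicted boundary mass: constant sentinels (no useful gradient)
        return Tensor(diag * len(point_kernels)), Tensor(diag)

    l_boundary = (yb * Tensor(d_target)).sum() / mass
    l_pd = Tensor(0.0)
    for d_pt, gibbs in point_kernels:
        wmap = yb * Tensor(gibbs)
        denom = wmap.sum()
        if float(denom.data) <= _EPS:
            l_pd = l_pd + Tensor(diag)
        else:
            l_pd = l_pd + (wmap * Tensor(d_pt)).sum() / denom
    return l_pd, l_boundary


def _point_kernels(
    shape: tuple[int, int], points: dict[int, ExtremePoints]
) -> list[tuple[np.ndarray, np.ndarray]]:
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    kernels = []
    for ep in points.values():
        for pt in (ep.p_top, ep.p_bottom, ep.p_left, ep.p_right):
            d = np.hypot(rows - pt[0], cols - pt[1])
            kernels.append((d, np.exp(-d / _SOFTMIN_T)))
    return kernels


def _target_boundary_distance(labels: np.ndarray) -> np.ndarray:
    bset = extract_boundary(labels > 0)
    if not bset.points:
        return np.full(labels.shape, math.hypot(*labels.shape))
    bm = np.zeros(labels.shape, dtype=bool)
    pts = bset.as_array()
    bm[pts[:, 0], pts[:, 1]] = True
    return ndimage.distance_transform_edt(~bm)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegmentationModel, path: Path, extra: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with config, seed and counts."""
    path = Path(path)
    arrays = model.state_arrays()
    np.savez(path, *arrays)
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "n_parameters": model.n_parameters(),
        "n_arrays": len(arrays),
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: Path) -> SegmentationModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["stage_channels"] = tuple(cfg["stage_channels"])
    config = ModelConfig(**cfg)
    model = SegmentationModel(config, seed=meta["seed"])
    with np.load(path) as data:
        model.load_state_arrays([data[k] for k in data.files])
    return model


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------


def _make_optimizer(model: SegmentationModel, config: TrainConfig) -> Adam:
    scale_params = [model.aggregator.scale_weights.raw]
    scale_ids = {id(p) for p in scale_params}
    base_params = [p for p in model.parameters() if id(p) not in scale_ids]
    return Adam(
        [
            {
                "params": base_params,
                "lr": config.base_lr,
                "weight_decay": config.weight_decay,
                "lr_scale": 1.0,
            },
            {
                "params": scale_params,
                "lr": 0.1 * config.base_lr,
                "weight_decay": 1e-4,
                "lr_scale": 0.1,
            },
        ]
    )


def _forward_batch(model, images: np.ndarray, forces: np.ndarray | None) -> Tensor:
    x = Tensor(images.transpose(0, 3, 1, 2))
    return model(x, force=forces)


def _validation_pass(model, dataset_dir, entries, config: TrainConfig):
    """Validation total loss (final weights, no curriculum) and mean metrics.

    The loss is computed against the same supervision the training loop sees
    (pseudo-labels by default), so early stopping never peeks at ground truth;
    the reported Dice/BF metrics, for monitoring only, use the true labels.
    """
    model.eval()
    losses, dices, bfs = [], [], []
    w = config.weights
    for entry in entries:
        image, labels, points = _load_sample(dataset_dir, entry)
        dense = (
            _load_pseudo(dataset_dir, entry)
            if config.supervision == "pseudo"
            else labels
        )
        img = image.astype(np.float64) / 255.0
        force = None
        if config.use_force:
            ff = compute_force_field(labels, alpha=config.force_alpha)
            force = ff.field.transpose(2, 0, 1)[None]
        with no_grad():
            prob = _forward_batch(model, img[None], force).data[0]
        target = dense > 0
        l_seg = segmentation_consistency_loss(prob, target, lam=w.lam)
        total = w.w_seg * l_seg
        if config.use_point_losses:
            pred_b = extract_boundary(prob >= config.threshold)
            target_b = extract_boundary(target)
            l_b = boundary_alignment_loss(pred_b, target_b)
            l_pd = sum(point_distance_loss(ep, pred_b) for ep in points.values())
            total += w.w_boundary * l_b + w.w_point * l_pd
        losses.append(total)
        report = evaluate_pair(
            prob >= config.threshold, labels > 0, config.bf_tolerance
        )
        dices.append(report.dice)
        bfs.append(report.bf)
    return float(np.mean(losses)), float(np.mean(dices)), float(np.mean(bfs))


def train(
    dataset_dir: Path,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    out_dir: Path | None = None,
) -> tuple[SegmentationModel, TrainingHistory]:
    """Run the full training loop on a dataset directory with a manifest.

    Dense targets come from pseudo-labels by default (``config.supervision``),
    keeping the setting weakly supervised: the only exact annotation signal
    is the extreme points (plus teacher-forced ground-truth force channels).
    The loss is L_seg plus curriculum-ramped differentiable surrogates of the
    boundary and point terms, gated by the ablation mode. Early stopping
    restores the best-validation-loss weights. Fully deterministic for a
    fixed config (pseudo-labels are generated once per dataset and cached).
    """
    entries = load_manifest(dataset_dir)
    train_entries = [e for e in entries if e["split"] == "train"]
    val_entries = [e for e in entries if e["split"] == "val"]
    if not train_entries or not val_entries:
        raise ValueError("manifest must contain non-empty train and val splits")
    if config.supervision == "pseudo":
        ensure_pseudo_labels(dataset_dir, train_entries + val_entries, seed=0)

    if model_config is None:
        model_config = ModelConfig(use_force_channels=config.use_force)
    if model_config.use_force_channels != config.use_force:
        model_config = replace(model_config, use_force_channels=config.use_force)
    model = build_model(model_config, seed=config.seed)
    optimizer = _make_optimizer(model, config)
    weights = config.weights

    history = TrainingHistory()
    best_loss = math.inf
    best_state: list[np.ndarray] | None = None
    since_improve = 0

    n_train = len(train_entries)
    for epoch in range(config.n_epochs):
        lr = cosine_lr(epoch, config.n_epochs, config.base_lr)
        optimizer.set_lr(lr)
        ramp = (
            curriculum_ramp(epoch, config.n_epochs)
            if weights.curriculum != "none"
            else 1.0
        )
        eff_w_b = weights.w_boundary * ramp
        eff_w_p = weights.w_point * ramp

        order = np.random.default_rng([config.seed, 777, epoch]).permutation(n_train)
        model.train()
        sums = np.zeros(4)  # l_pd, l_boundary, l_seg, l_total
        n_batches = 0
        for start in range(0, n_train, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            images, targets_list, gt_list, forces = [], [], [], []
            for j, idx in enumerate(batch_idx):
                entry = train_entries[idx]
                image, gt_labels, _ = _load_sample(dataset_dir, entry)
                dense = (
                    _load_pseudo(dataset_dir, entry)
                    if config.supervision == "pseudo"
                    else gt_labels
                )
                img, (gt_aug, dense_aug) = _augment_joint(
                    image,
                    [gt_labels, dense],
                    seed=[config.seed, epoch, int(idx)],
                    rotation_degrees=config.rotation_degrees,
                    hflip_prob=config.hflip_prob,
                    elastic_grid=config.elastic_grid,
                    elastic_sigma=config.elastic_sigma,
                    gamma_range=config.gamma_range,
                    scale_jitter=config.scale_jitter,
                )
                images.append(img)
                targets_list.append(dense_aug)
                gt_list.append(gt_aug)
                if config.use_force:
                    forces.append(
                        compute_force_field(gt_aug, alpha=config.force_alpha)
                        .field.transpose(2, 0, 1)
                    )
            x = np.stack(images)
            force = np.stack(forces) if forces else None

            prob = _forward_batch(model, x, force)

            l_seg_t = Tensor(0.0)
            l_pd_t = Tensor(0.0)
            l_b_t = Tensor(0.0)
            for j, (dense_aug, gt_aug) in enumerate(zip(targets_list, gt_list)):
                p = prob[j]
                l_seg_t = l_seg_t + _sample_seg_loss(p, dense_aug > 0, weights.lam)
                if config.use_point_losses:
                    # annotated extreme points, recomputed on the transformed
                    # ground-truth instances (the annotation signal itself)
                    pts = {
                        int(i): extract_extreme_points(gt_aug == i)
                        for i in np.unique(gt_aug)
                        if i > 0
                    }
                    l_pd_j, l_b_j = _sample_weak_losses(
                        p,
                        _target_boundary_distance(dense_aug),
                        _point_kernels(gt_aug.shape, pts),
                    )
                    l_pd_t = l_pd_t + l_pd_j
                    l_b_t = l_b_t + l_b_j
            k = float(len(targets_list))
            l_seg_t = l_seg_t * (1.0 / k)
            l_pd_t = l_pd_t * (1.0 / k)
            l_b_t = l_b_t * (1.0 / k)
            total = (
                weights.w_seg * l_seg_t + eff_w_b * l_b_t + eff_w_p * l_pd_t
            )
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: seg={l_seg_t.data}, "
                    f"boundary={l_b_t.data}, pd={l_pd_t.data}"
                )
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            sums += [
                float(l_pd_t.data),
                float(l_b_t.data),
                float(l_seg_t.data),
                float(total.data),
            ]
            n_batches += 1

        val_loss, val_dice, val_bf = _validation_pass(
            model, dataset_dir, val_entries, config
        )
        history.records.append(
            EpochRecord(
                epoch=epoch,
                lr=lr,
                l_pd=sums[0] / n_batches,
                l_boundary=sums[1] / n_batches,
                l_seg=sums[2] / n_batches,
                l_total=sums[3] / n_batches,
                eff_w_boundary=eff_w_b,
                eff_w_point=eff_w_p,
                val_loss=val_loss,
                val_dice=val_dice,
                val_bf=val_bf,
            )
        )
        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_state = [a.copy() for a in model.state_arrays()]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                history.stopped_early = True
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        history.save_csv(out_dir / "history.csv")
        save_checkpoint(
            model,
            out_dir / "model.npz",
            extra={
                "train_config": _config_json(config),
                "best_epoch": history.best_epoch,
                "stopped_early": history.stopped_early,
            },
        )
    return model, history


def _config_json(config: TrainConfig) -> dict:
    d = asdict(config)
    d["weights"] = asdict(config.weights)
    return d


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------


def evaluate_split(
    model: SegmentationModel,
    dataset_dir: Path,
    entries: Sequence[dict],
    threshold: float = 0.5,
    bf_tolerance: float = 2.0,
    two_pass: bool = True,
) -> tuple[float, float]:
    """Mean (dice, bf) of `segment` output over the given manifest entries."""
    dices, bfs = [], []
    for entry in entries:
        image, labels, _ = _load_sample(dataset_dir, entry)
        prob = segment(model, image, two_pass=two_pass, threshold=threshold)
        report = evaluate_pair(prob >= threshold, labels > 0, bf_tolerance)
        dices.append(report.dice)
        bfs.append(report.bf)
    return float(np.mean(dices)), float(np.mean(bfs))


def run_ablation(
    dataset_dir: Path,
    config: TrainConfig,
    modes: Sequence[str] = ABLATION_MODES,
    model_config: ModelConfig | None = None,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Train one model per ablation mode on shared data/seeds.

    Returns a dataframe with one row per mode: mean test-split Dice and
    Boundary-F1. `model_config` defaults to the compact
    :meth:`ModelConfig.ablation_scale` variant suitable for CPU runs.
    """
    if len(modes) < 2:
        raise ValueError("need at least two modes to ablate")
    for m in modes:
        if m not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode: {m}")
    entries = load_manifest(dataset_dir)
    test_entries = [e for e in entries if e["split"] == "test"]
    if not test_entries:
        raise ValueError("manifest must contain a non-empty test split")

    rows = []
    for mode in modes:
        cfg = replace(config, ablation_mode=mode)
        mc = (
            ModelConfig.ablation_scale(use_force_channels=cfg.use_force)
            if model_config is None
            else replace(model_config, use_force_channels=cfg.use_force)
        )
        mode_out = Path(out_dir) / mode if out_dir is not None else None
        model, history = train(dataset_dir, cfg, model_config=mc, out_dir=mode_out)
        dice, bf = evaluate_split(
            model,
            dataset_dir,
            test_entries,
            threshold=cfg.threshold,
            bf_tolerance=cfg.bf_tolerance,
            two_pass=cfg.use_force,
        )
        rows.append(
            {
                "mode": mode,
                "dice": dice,
                "bf": bf,
                "best_epoch": history.best_epoch,
                "stopped_early": history.stopped_early,
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "ablation.csv", index=False)
    return df
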