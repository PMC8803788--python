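"""Supervised training of the enhancement model on paired volumes.

Input volumes are noisy, partially converged OSEM reconstructions at mixed
scan durations; the target for every pair is the full-duration BSREM
reconstruction of the same case, so a single generic model learns to deal
with several noise levels at once.

Pipeline per pair: transverse crop to the body bounding box (never
removing more than ``crop_fraction_max`` of a transverse axis), padding to
the patch grid, and axial division into equally spaced patches that cover
every slice at least once; input and target are patched with identical
placements.  Training minimises the mean squared error between
``input + residue`` and the target patch with the Adam optimiser, shuffling
the patches each epoch.  After every epoch the validation loss and the
validation SUV metrics (lesion SUV_max percent difference and liver-noise
percent difference against the target) are recorded; the returned weights
are the checkpoint of the epoch minimising the sum of the validation-MSE
rank and the lesion-SUV_max-difference rank (earlier epoch on ties).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from . import evalsuite, network
from .recon import ImageVolume

logger = logging.getLogger("petdle.training")

__all__ = [
    "TrainingConfig",
    "TrainingPair",
    "TrainingRecord",
    "CropInfo",
    "crop_to_body",
    "uncrop",
    "extract_patches",
    "reassemble_patches",
    "Adam",
    "train_model",
    "select_best_epoch",
]


@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 4
    patch_size: tuple[int, int, int] = (60, 48, 24)
    axial_stride: int = 24
    crop_fraction_max: float = 0.4
    seed: int = 0
    validation_pairs: int = 1

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.max_epochs > 100:
            logger.warning("max_epochs %d exceeds the default cap of 100",
                           self.max_epochs)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.crop_fraction_max <= 0.4):
            raise ValueError("crop_fraction_max must lie in [0, 0.4]")
        if self.validation_pairs < 1:
            raise ValueError("validation_pairs must be >= 1")


@dataclass
class TrainingPair:
    """One (noisy input, clean target) volume pair, with optional ROIs for
    the validation SUV metrics."""

    input: ImageVolume
    target: ImageVolume
    liver_vois: list | None = None
    lesion_centers: list | None = None
    case_id: str = ""


@dataclass
class TrainingRecord:
    """Append-only per-epoch log plus the chosen checkpoint index."""

    epochs: list = field(default_factory=list)
    permutations: list = field(default_factory=list)
    chosen_epoch: int = -1
    seed: int = 0

    def append(self, **metrics):
        metrics["epoch"] = len(self.epochs)
        self.epochs.append(metrics)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TrainingRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# cropping

@dataclass(frozen=True)
class CropInfo:
    offsets: tuple[int, int, int]
    cropped_shape: tuple[int, int, int]
    original_shape: tuple[int, int, int]


def crop_to_body(values: np.ndarray, crop_fraction_max: float = 0.4):
    """Transverse crop to the body bounding box, capped per axis.

    The body mask is a threshold at 5% of the volume maximum followed by
    largest-connected-component selection.  Only the two transverse axes
    are cropped, each by at most ``crop_fraction_max`` of its extent; the
    axial extent is untouched.  Returns (cropped values, CropInfo).
    """
    values = np.asarray(values)
    shape = values.shape
    mask = values >= 0.05 * values.max() if values.max() > 0 else np.zeros(shape, bool)
    if not mask.any():
        logger.warning("crop_to_body: empty body mask, no crop applied")
        return values.copy(), CropInfo((0, 0, 0), shape, shape)
    labels, n = ndimage.label(mask)
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1))) + 1
        mask = labels == largest
    lo_hi = []
    for axis in (0, 1):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        n_ax = shape[axis]
        max_remove = int(np.floor(crop_fraction_max * n_ax))
        removed = n_ax - (hi - lo)
        if removed > max_remove:
            # cap binds: expand the box (symmetrically where possible)
            # until exactly max_remove voxels are dropped on this axis
            target_width = n_ax - max_remove
            extra = target_width - (hi - lo)
            lo = max(0, lo - (extra + 1) // 2)
            hi = min(n_ax, lo + target_width)
            lo = hi - target_width
        lo_hi.append((lo, hi))
    (x0, x1), (y0, y1) = lo_hi
    cropped = values[x0:x1, y0:y1, :].copy()
    return cropped, CropInfo((x0, y0, 0), cropped.shape, shape)


def uncrop(values: np.ndarray, info: CropInfo) -> np.ndarray:
    """Invert :func:`crop_to_body`: embed at the recorded offsets, zeros
    outside."""
    out = np.zeros(info.original_shape, dtype=values.dtype)
    x0, y0, z0 = info.offsets
    sx, sy, sz = values.shape
    out[x0:x0 + sx, y0:y0 + sy, z0:z0 + sz] = values
    return out


# ---------------------------------------------------------------------------
# patch extraction

def _axis_offsets(extent: int, patch: int, max_spacing: int) -> list[int]:
    if patch > extent:
        raise ValueError(f"patch size {patch} exceeds extent {extent}")
    if patch == extent:
        return [0]
    span = extent - patch
    k = int(np.ceil(span / max_spacing)) + 1
    return [int(round(i * span / (k - 1))) for i in range(k)]


def extract_patches(values: np.ndarray, patch_size, axial_stride: int):
    """Equally spaced patches covering every voxel at least once.

    The axial axis is divided with spacing at most ``axial_stride`` (and
    at most the axial patch extent); transverse axes use the patch extent
    as the spacing cap.  Minimal patch count per axis; the last patch ends
    at the final voxel.  Returns (patches, placements) where placements
    are (x0, y0, z0) corner offsets sufficient for exact reassembly.
    """
    if axial_stride <= 0:
        raise ValueError("axial_stride must be positive")
    values = np.asarray(values)
    px, py, pz = patch_size
    offs_x = _axis_offsets(values.shape[0], px, px)
    offs_y = _axis_offsets(values.shape[1], py, py)
    offs_z = _axis_offsets(values.shape[2], pz, min(axial_stride, pz))
    placements = [(x, y, z) for z in offs_z for y in offs_y for x in offs_x]
    patches = [values[x:x + px, y:y + py, z:z + pz] for x, y, z in placements]
    return patches, placements


def reassemble_patches(patches, placements, shape) -> np.ndarray:
    """Overlap-averaged reassembly (uniform weights)."""
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    for patch, (x, y, z) in zip(patches, placements):
        px, py, pz = patch.shape
        acc[x:x + px, y:y + py, z:z + pz] += patch
        cnt[x:x + px, y:y + py, z:z + pz] += 1.0
    if (cnt == 0).any():
        raise ValueError("placements do not cover the volume")
    return acc / cnt


def _pad_to(values: np.ndarray, patch_size):
    """Zero-pad symmetrically so each axis is at least the patch extent."""
    target = np.maximum(values.shape, patch_size)
    lo = (target - np.array(values.shape)) // 2
    hi = target - values.shape - lo
    return np.pad(values, [(l, h) for l, h in zip(lo, hi)])


# ---------------------------------------------------------------------------
# optimiser

class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + eps)


# ---------------------------------------------------------------------------
# training loop

def _prepare_pair(pair: TrainingPair, cfg: TrainingConfig):
    cropped_t, info = crop_to_body(pair.target.values, cfg.crop_fraction_max)
    x0, y0, _ = info.offsets
    sx, sy, _ = info.cropped_shape
    cropped_i = pair.input.values[x0:x0 + sx, y0:y0 + sy, :]
    inp = _pad_to(cropped_i, cfg.patch_size)
    tgt = _pad_to(cropped_t, cfg.patch_size)
    p_in, placements = extract_patches(inp, cfg.patch_size, cfg.axial_stride)
    p_tg, _ = extract_patches(tgt, cfg.patch_size, cfg.axial_stride)
    return list(zip(p_in, p_tg))


def _validation_suv_metrics(model, val_pairs):
    """Mean |lesion SUV_max % difference| and mean |liver-noise % difference|
    of the enhanced validation volumes against their targets."""
    suv_diffs, noise_diffs = [], []
    for pair in val_pairs:
        if not pair.lesion_centers and not pair.liver_vois:
            continue
        enhanced = np.clip(network.apply_to_volume(model, pair.input.values), 0, None)
        tgt = pair.target.values
        if pair.lesion_centers:
            for c in pair.lesion_centers:
                ref = evalsuite.segment_lesion(tgt, c).suv_max
                ser = evalsuite.segment_lesion(enhanced, c).suv_max
                suv_diffs.append(abs(evalsuite.percent_difference(ser, ref)))
        if pair.liver_vois:
            ref = evalsuite.voi_stats(tgt, pair.liver_vois).liver_noise_sd
            ser = evalsuite.voi_stats(enhanced, pair.liver_vois).liver_noise_sd
            noise_diffs.append(abs(evalsuite.percent_difference(ser, ref)))
    suv = float(np.mean(suv_diffs)) if suv_diffs else float("nan")
    noise = float(np.mean(noise_diffs)) if noise_diffs else float("nan")
    return suv, noise


def select_best_epoch(record: TrainingRecord) -> int:
    """Rank-sum stopping rule over the two validation criteria.

    Epochs are ranked by validation MSE and by the validation lesion
    SUV_max mean absolute percent difference; the chosen epoch minimises
    the rank sum, ties resolved in favour of the earlier epoch.  If the
    SUV metric is unavailable the MSE ranking alone decides.
    """
    if not record.epochs:
        raise ValueError("no recorded epochs")
    mse = np.array([e["val_mse"] for e in record.epochs])
    suv = np.array([e.get("val_suv_pct", np.nan) for e in record.epochs])
    ranks = rankdata(mse)
    if not np.isnan(suv).any():
        ranks = ranks + rankdata(suv)
    return int(np.argmin(ranks))  # argmin takes the first (earliest) minimum


def train_model(pairs, net_config: network.NetworkConfig,
                train_config: TrainingConfig):
    """Train the enhancement model; returns (model, TrainingRecord).

    The last ``train_config.validation_pairs`` entries of ``pairs`` form
    the validation set.  Fully reproducible given the seeds in the two
    configs; per-epoch checkpoints are kept in memory and the weights of
    the selected epoch are restored before returning.
    """
    cfg = train_config
    if len(pairs) < cfg.validation_pairs + 1:
        raise ValueError("need at least one training and one validation pair")
    val_pairs = pairs[-cfg.validation_pairs:]
    trn_pairs = pairs[:-cfg.validation_pairs]

    trn_patches = [pt for pair in trn_pairs for pt in _prepare_pair(pair, cfg)]
    val_patches = [pt for pair in val_pairs for pt in _prepare_pair(pair, cfg)]
    model = network.build_network(net_config)
    opt = Adam(model.params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    record = TrainingRecord(seed=cfg.seed)
    checkpoints = []

    n = len(trn_patches)
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        perm = rng.permutation(n)
        record.permutations.append(perm.tolist())
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = np.stack([trn_patches[i][0] for i in idx])
            yb = np.stack([trn_patches[i][1] for i in idx])
            res = model.forward_residue(xb, training=True)
            err = (xb + res) - yb
            loss = float(np.mean(err.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{start // cfg.batch_size}")
            losses.append(loss)
            model.backward((2.0 / err.size) * err)
            opt.step(model.grads)
        val_losses = []
        for xv, yv in val_patches:
            rv = model.forward_residue(xv, training=False)
            val_losses.append(float(np.mean(((xv + rv) - yv).astype(np.float64) ** 2)))
        val_suv, val_noise = _validation_suv_metrics(model, val_pairs)
        record.append(train_mse=float(np.mean(losses)),
                      val_mse=float(np.mean(val_losses)),
                      val_suv_pct=val_suv,
                      val_noise_pct=val_noise,
                      seconds=time.time() - t0)
        checkpoints.append(model.copy_state())
        logger.info("epoch %d: train MSE %.5g, val MSE %.5g, val SUV%% %.3g",
                    epoch, record.epochs[-1]["train_mse"],
                    record.epochs[-1]["val_mse"], val_suv)

    best = select_best_epoch(record)
    record.chosen_epoch = best
    model.load_state_arrays(checkpoints[best])
    return model, record
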