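"""Per-patient splits, augmentation, patch sampling and stage training.

Splits are drawn per patient, never per scan, with a fixed held-out test
set and three independently re-drawn train/validation splits over the
remaining patients ("bootstrapped" folds).  Each stage of the cascade is
trained on sampled, augmented patches (the tumor stage trains on whole
crops) with a compound soft-Dice + cross-entropy objective, Adam, and
best-validation-Dice checkpoint selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .nn import Adam, NetworkConfig, UNet3D, build_model, dice_ce_loss
from .evaluation import dice

__all__ = ["SplitPlan", "make_splits", "AugmentConfig", "augment",
           "sample_patch", "TrainConfig", "train_stage"]


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitPlan:
    """Per-patient fold assignments with one shared held-out test set."""

    test: tuple[str, ...]
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, val) per fold
    seed: int

    def bucket_of(self, patient_id: str, fold: int) -> str:
        if patient_id in self.test:
            return "test"
        train, val = self.folds[fold]
        if patient_id in train:
            return "train"
        if patient_id in val:
            return "val"
        raise KeyError(patient_id)


def make_splits(patient_ids, fractions=(0.70, 0.15, 0.15), n_folds: int = 3,
                seed: int = 0) -> SplitPlan:
    """Draw a split plan: fixed test set, re-drawn train/val per fold.

    ``fractions`` are (train, val, test) shares of the whole cohort; the
    train/val partition is re-drawn independently per fold from the
    non-test patients, so folds overlap — three separate opinions on the
    same task rather than rotated cross-validation.
    """
    ids = list(patient_ids)
    n = len(ids)
    f_train, f_val, f_test = fractions
    n_test = round(n * f_test)
    n_train = round(n * f_train)
    if n_test < 1 or n_train < 1 or n - n_test - n_train < 1:
        raise ValueError(f"too few patients ({n}) for fractions {fractions}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    test = tuple(perm[:n_test])
    pool = perm[n_test:]
    folds = []
    for _ in range(n_folds):
        fperm = [pool[i] for i in rng.permutation(len(pool))]
        folds.append((tuple(fperm[:n_train]), tuple(fperm[n_train:])))
    return SplitPlan(test=test, folds=tuple(folds), seed=seed)


# ---------------------------------------------------------------------------
# augmentation

@dataclass
class AugmentConfig:
    """Stochastic training-time transforms with per-transform probabilities.

    Spatial transforms hit every channel and the target identically (with
    nearest-neighbour interpolation for masks); intensity noise touches
    intensity channels only; erosion/dilation touches duct channels only —
    never the CT channel.
    """

    p_flip: float = 0.0
    flip_axes: tuple[int, ...] = (0, 1)
    p_rotate: float = 0.5
    rotation_deg: float = 15.0
    p_elastic: float = 0.25
    elastic_sigma: float = 4.0
    elastic_alpha: float = 2.0
    p_duct_morph: float = 0.0
    duct_morph_radius: int = 1
    p_gauss: float = 0.0
    gauss_sd: float = 0.02
    p_poisson: float = 0.0
    poisson_amp: float = 0.02

    @classmethod
    def pancreas_duct(cls) -> "AugmentConfig":
        """Rotations and elastic deformations (pancreas/duct stages)."""
        return cls()

    @classmethod
    def tumor(cls) -> "AugmentConfig":
        """Extended suite for the tumor stage: flips, rotations, duct
        erosion/dilation, elastic deformation, Gaussian and Poisson noise."""
        return cls(p_flip=0.5, p_duct_morph=0.5, p_gauss=0.5, p_poisson=0.25)

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(p_rotate=0.0, p_elastic=0.0)


_VALID_TAGS = {"intensity", "mask", "duct"}


def augment(x: np.ndarray, target: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator, channel_tags) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured transforms to a (channels, target) sample.

    ``channel_tags`` labels each input channel ``intensity``, ``mask`` or
    ``duct``; the target is always treated as a mask.  With all
    probabilities zero the sample is returned bit-identical.
    """
    tags = list(channel_tags)
    if len(tags) != x.shape[0] or any(t not in _VALID_TAGS for t in tags):
        raise ValueError(f"need one tag per channel from {_VALID_TAGS}, got {tags}")
    x = np.array(x, dtype=float)      # copy: never mutate the caller's sample
    target = np.array(target)
    target_is_int = np.issubdtype(target.dtype, np.integer) or target.dtype == bool

    def spatial(fn_intensity, fn_mask):
        nonlocal x, target
        x = np.stack([
            fn_intensity(c) if t == "intensity" else fn_mask(c) for c, t in zip(x, tags)
        ])
        target = fn_mask(target)

    if cfg.p_flip > 0 and rng.random() < cfg.p_flip:
        axis = int(rng.choice(cfg.flip_axes))
        spatial(lambda c: np.flip(c, axis), lambda c: np.flip(c, axis))

    if cfg.p_rotate > 0 and rng.random() < cfg.p_rotate:
        ang = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        spatial(
            lambda c: ndi.rotate(c, ang, axes=(0, 1), reshape=False, order=1, mode="nearest"),
            lambda c: ndi.rotate(c.astype(float), ang, axes=(0, 1), reshape=False,
                                 order=0, mode="nearest"),
        )

    if cfg.p_elastic > 0 and rng.random() < cfg.p_elastic:
        shape = x.shape[1:]
        disp = [
            ndi.gaussian_filter(rng.normal(0, 1, shape), cfg.elastic_sigma) * cfg.elastic_alpha
            for _ in range(3)
        ]
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        coords = np.stack([g + d for g, d in zip(grids, disp)])

        def warp(c, order):
            return ndi.map_coordinates(c.astype(float), coords, order=order, mode="nearest")

        spatial(lambda c: warp(c, 1), lambda c: warp(c, 0))

    if cfg.p_duct_morph > 0:
        for i, t in enumerate(tags):
            if t == "duct" and rng.random() < cfg.p_duct_morph:
                op = ndi.binary_dilation if rng.random() < 0.5 else ndi.binary_erosion
                r = int(rng.integers(1, cfg.duct_morph_radius + 1))
                x[i] = op(x[i] > 0.5, iterations=r).astype(float)

    intensity_idx = [i for i, t in enumerate(tags) if t == "intensity"]
    if cfg.p_gauss > 0 and intensity_idx and rng.random() < cfg.p_gauss:
        for i in intensity_idx:
            x[i] = x[i] + rng.normal(0, cfg.gauss_sd, x[i].shape)
    if cfg.p_poisson > 0 and intensity_idx and rng.random() < cfg.p_poisson:
        lam = 4.0
        for i in intensity_idx:
            x[i] = x[i] + cfg.poisson_amp * (rng.poisson(lam, x[i].shape) - lam) / np.sqrt(lam)

    if target_is_int:
        target = np.round(target).astype(np.int64)
    return x, target


# ---------------------------------------------------------------------------
# patch sampling

def sample_patch(volume: np.ndarray, target: np.ndarray, patch_size,
                 fg_fraction: float, rng: np.random.Generator):
    """Draw one training patch, optionally centred on a foreground voxel.

    With probability ``fg_fraction`` the centre is a uniformly drawn
    foreground voxel of the target (falling back to uniform when the
    target is empty); the patch start is clamped in-bounds.
    """
    if volume.ndim == 3:
        volume = volume[None]
    shape = volume.shape[1:]
    fg = np.argwhere(target > 0)
    if fg.size and rng.random() < fg_fraction:
        center = fg[int(rng.integers(len(fg)))]
    else:
        center = [int(rng.integers(s)) for s in shape]
    start = [
        int(np.clip(center[a] - patch_size[a] // 2, 0, shape[a] - patch_size[a]))
        for a in range(3)
    ]
    sl = tuple(slice(start[a], start[a] + patch_size[a]) for a in range(3))
    return volume[(slice(None),) + sl], target[sl]


# ---------------------------------------------------------------------------
# stage training

@dataclass
class TrainConfig:
    net: NetworkConfig = field(default_factory=NetworkConfig)
    steps: int = 150
    lr: float = 3e-3
    fg_fraction: float = 0.7
    patch_size: tuple[int, int, int] | None = (16, 16, 8)  # None -> whole sample
    val_interval: int = 25
    augment: AugmentConfig = field(default_factory=AugmentConfig.none)
    seed: int = 0


def train_stage(samples, channel_tags, config: TrainConfig, stage: str = "stage",
                fold: int = 0, val_samples=None) -> tuple[UNet3D, pd.DataFrame]:
    """Optimize one stage model on (input, target) sample pairs.

    ``samples`` is a list of ``(channels, target)`` arrays in stage space
    (e.g. normalized low-resolution volumes for the coarse stage, crops
    for the others).  Returns the model restored to its best validation
    Dice checkpoint together with the per-step training log.
    """
    if not samples:
        raise ValueError("empty training sample list")
    head = config.net.head
    rng = np.random.default_rng(config.seed)
    model = build_model(config.net, seed=config.seed,
                        training_meta={"stage": stage, "fold": fold, "seed": config.seed})
    opt = Adam(model.params(), lr=config.lr)
    log = []
    best = (-1.0, None)

    def val_dice() -> float:
        if not val_samples:
            return float("nan")
        ds = []
        for x, t in val_samples:
            prob = model.predict_proba(np.asarray(x, dtype=float))
            if head == "sigmoid":
                ds.append(dice(prob[0] >= 0.5, np.asarray(t) > 0))
            else:
                pred = prob.argmax(axis=0)
                for c in range(1, config.net.out_channels):
                    ds.append(dice(pred == c, np.asarray(t) == c))
        return float(np.mean(ds))

    for step in range(config.steps):
        x, t = samples[int(rng.integers(len(samples)))]
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if config.patch_size is not None:
            x, t = sample_patch(x, np.asarray(t), config.patch_size, config.fg_fraction, rng)
        x, t = augment(x, np.asarray(t), config.augment, rng, channel_tags)
        logits = model.forward_logits(x, cache=True)
        loss, dz = dice_ce_loss(logits, t, head=head)
        model.zero_grad()
        model.backward(dz)
        opt.step()
        entry = {"step": step, "loss": loss}
        if val_samples and (step + 1) % config.val_interval == 0:
            vd = val_dice()
            entry["val_dice"] = vd
            if vd > best[0]:
                best = (vd, [p.copy() for p, _ in model.params()])
        log.append(entry)

    if best[1] is not None:
        for (p, _), saved in zip(model.params(), best[1]):
            p[...] = saved
        model.training_meta["best_val_dice"] = best[0]
    return model, pd.DataFrame(log)
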