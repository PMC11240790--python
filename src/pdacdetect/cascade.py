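"""The four-stage coarse-to-fine detection workflow.

Stage 1 localizes the pancreas on a low-resolution rendering of the whole
scan; stage 2 segments it precisely on a high-resolution crop around the
located centre; stage 3 segments the common bile duct and pancreatic duct
on that crop (one multi-label softmax model or two single-label models)
and removes duct components that do not attach to the pancreas; stage 4
feeds the CT crop stacked with the pancreas and duct masks — the
"secondary feature" channels — to the tumor model in a single full-crop
forward pass.  Per-fold tumor maps are averaged voxel-wise (mean before
max); the case score is the maximum voxel of the ensemble map and the
case is called positive when the score reaches the operating threshold
(default 0.61).

Every stage accepts the sentinel ``ORACLE`` in place of trained models, in
which case the ground-truth structure — put through exactly the same
resampling/cropping plumbing — stands in for the prediction.  With oracles
at every stage the cascade must reproduce the ground truth with Dice 1.0;
this is the plumbing-correctness contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .patch_engine import TilingSpec, binarize, largest_component, sliding_window_predict, _STRUCTS
from .volume_core import (CropRegion, LabelMap, Volume, extract_crop,
                          map_index_between_spacings, normalize_hu, resample)

__all__ = ["ORACLE", "StageBundle", "DetectionResult", "PancreasNotLocatedError",
           "locate_pancreas", "segment_pancreas_fine", "segment_ducts",
           "filter_ducts_by_pancreas", "detect_tumor", "ensemble_and_classify",
           "run_pipeline", "patient_score", "phantom_scale_bundle_geometry"]

#: sentinel replacing a fold-model list: use ground truth through the same plumbing
ORACLE = "oracle"


class PancreasNotLocatedError(RuntimeError):
    pass


@dataclass
class StageBundle:
    """Models plus geometry for the full cascade.

    Each stage holds one model per fold (or :data:`ORACLE`).  ``duct_mode``
    is ``"multi"`` (one softmax model: background / common bile duct /
    pancreatic duct) or ``"single"`` (two binary models per fold, given as
    ``ducts=(cbd_models, pd_models)``).
    """

    coarse_pancreas: object = ORACLE
    fine_pancreas: object = ORACLE
    ducts: object = ORACLE
    tumor: object = ORACLE
    duct_mode: str = "multi"
    low_spacing: tuple[float, float, float] = (1.37, 1.37, 2.0)
    high_spacing: tuple[float, float, float] = (0.68, 0.68, 1.0)
    crop_size: tuple[int, int, int] = (256, 256, 192)
    pancreas_tiling: TilingSpec = field(default_factory=lambda: TilingSpec((128, 128, 64)))
    duct_tiling: TilingSpec = field(default_factory=lambda: TilingSpec((128, 128, 128)))
    threshold: float = 0.61
    mask_threshold: float = 0.5
    attach_radius: int = 2
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.duct_mode not in ("multi", "single"):
            raise ValueError(f"duct_mode must be 'multi' or 'single', got {self.duct_mode!r}")
        counts = set()
        for stage in (self.coarse_pancreas, self.fine_pancreas, self.tumor):
            if stage != ORACLE:
                counts.add(len(stage))
        if self.ducts != ORACLE:
            if self.duct_mode == "single":
                counts.update(len(m) for m in self.ducts)
            else:
                counts.add(len(self.ducts))
        if len(counts) > 1:
            raise ValueError(f"all stages must share one fold count, got {sorted(counts)}")

    @property
    def n_folds(self) -> int:
        for stage in (self.coarse_pancreas, self.fine_pancreas, self.tumor):
            if stage != ORACLE:
                return len(stage)
        if self.ducts != ORACLE:
            return len(self.ducts if self.duct_mode == "multi" else self.ducts[0])
        return 1


def phantom_scale_bundle_geometry(shape=(48, 48, 48)) -> dict:
    """Geometry-similar scale-down of the full-scale cascade settings.

    Native phantom resolution plays the high-resolution role; the coarse
    stage works at twice the spacing, mirroring the full-scale design.
    """
    return dict(
        low_spacing=(2.0, 2.0, 2.0),
        high_spacing=(1.0, 1.0, 1.0),
        crop_size=(32, 32, 24),
        pancreas_tiling=TilingSpec((16, 16, 8), (8, 8, 8)),
        duct_tiling=TilingSpec((16, 16, 16), (8, 8, 8)),
    )


@dataclass
class DetectionResult:
    case_id: str
    tumor_prob: np.ndarray
    per_fold_scores: list[float]
    case_score: float
    call: bool
    masks: dict
    crop_region: CropRegion | None
    dscs: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "case_id": self.case_id,
            "case_score": self.case_score,
            "call": bool(self.call),
            "per_fold_scores": [float(s) for s in self.per_fold_scores],
            "dscs": {k: float(v) for k, v in self.dscs.items()},
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# helpers

def _pad_to_patch(vol: np.ndarray, patch) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Symmetrically pad channel-first data so each axis >= patch size."""
    pads = [(0, 0)]
    for a in range(3):
        short = max(0, patch[a] - vol.shape[a + 1])
        before = short // 2
        pads.append((before, short - before))
    return np.pad(vol, pads), pads


def _unpad(arr: np.ndarray, pads, shape) -> np.ndarray:
    sl = [slice(None)]
    for a in range(3):
        sl.append(slice(pads[a + 1][0], pads[a + 1][0] + shape[a]))
    return arr[tuple(sl)]


def _fold_mean_sliding(models, data: np.ndarray, spec: TilingSpec, channel: int = 0) -> np.ndarray:
    """Mean over fold models of sliding-window predictions (one channel)."""
    if data.ndim == 3:
        data = data[None]
    padded, pads = _pad_to_patch(data, spec.patch_size)
    acc = None
    for m in models:
        pred = sliding_window_predict(m, padded, spec)
        acc = pred if acc is None else acc + pred
    acc /= len(models)
    return _unpad(acc, pads, data.shape[1:])[channel]


def _gt_structure(gt: LabelMap, structure: str, spacing) -> np.ndarray:
    """Ground-truth structure mask resampled (nearest) to a working spacing."""
    m = gt.mask(structure).astype(np.uint8)
    v = Volume(m, spacing=gt.spacing, origin=gt.origin)
    if tuple(spacing) != tuple(gt.spacing):
        v = resample(v, spacing, mode="nearest")
    return v.data.astype(bool)


def _extract_by_region(v: Volume, region: CropRegion, fill: float = 0.0) -> tuple[np.ndarray, CropRegion]:
    start, size = region.start, region.size
    out = np.full(size, fill, dtype=float)
    src_lo = [max(start[a], 0) for a in range(3)]
    src_hi = [min(start[a] + size[a], v.shape[a]) for a in range(3)]
    dst_lo = [src_lo[a] - start[a] for a in range(3)]
    dst_hi = [dst_lo[a] + (src_hi[a] - src_lo[a]) for a in range(3)]
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = np.asarray(
        v.data
    )[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return out, region


# ---------------------------------------------------------------------------
# stages

def locate_pancreas(ct: Volume, coarse_models, bundle: StageBundle,
                    gt: LabelMap | None = None) -> tuple[int, int, int]:
    """Coarse localization: centroid of the largest low-resolution pancreas
    component, mapped to the high-resolution grid."""
    low = normalize_hu(resample(ct, bundle.low_spacing, mode="linear"))
    if coarse_models == ORACLE:
        if gt is None:
            raise ValueError("oracle coarse stage requires ground truth")
        prob = _gt_structure(gt, "pancreas", bundle.low_spacing).astype(float)
    else:
        prob = _fold_mean_sliding(coarse_models, low.data, bundle.pancreas_tiling)
    mask = largest_component(binarize(prob, bundle.mask_threshold), bundle.connectivity)
    if not mask.any():
        raise PancreasNotLocatedError("pancreas not located in coarse stage")
    centroid = tuple(int(round(c)) for c in ndi.center_of_mass(mask))
    return map_index_between_spacings(
        centroid, bundle.low_spacing, bundle.high_spacing, ct.origin, ct.origin
    )


def segment_pancreas_fine(ct_high: Volume, center, fine_models, bundle: StageBundle,
                          gt: LabelMap | None = None) -> tuple[np.ndarray, CropRegion, np.ndarray]:
    """Fine pancreas probability on the high-resolution crop around ``center``.

    Returns (pancreas probability grid, crop region, normalized CT crop).
    """
    center = tuple(min(max(int(c), 0), ct_high.shape[a] - 1) for a, c in enumerate(center))
    norm = normalize_hu(ct_high)
    crop, region = extract_crop(norm, center, bundle.crop_size, fill=0.0)
    if fine_models == ORACLE:
        if gt is None:
            raise ValueError("oracle fine stage requires ground truth")
        gm = _gt_structure(gt, "pancreas", bundle.high_spacing)
        prob, _ = _extract_by_region(Volume(gm.astype(np.uint8), bundle.high_spacing), region)
    else:
        prob = _fold_mean_sliding(fine_models, crop.data, bundle.pancreas_tiling)
    return prob, region, crop.data


def segment_ducts(crop: np.ndarray, duct_models, bundle: StageBundle,
                  gt: LabelMap | None = None, region: CropRegion | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Duct probabilities (common bile duct, pancreatic duct) on the crop."""
    if duct_models == ORACLE:
        if gt is None or region is None:
            raise ValueError("oracle duct stage requires ground truth and crop region")
        cbd = _gt_structure(gt, "common_bile_duct", bundle.high_spacing)
        pdm = _gt_structure(gt, "pancreatic_duct", bundle.high_spacing)
        cbd_p, _ = _extract_by_region(Volume(cbd.astype(np.uint8), bundle.high_spacing), region)
        pd_p, _ = _extract_by_region(Volume(pdm.astype(np.uint8), bundle.high_spacing), region)
        return cbd_p, pd_p
    if bundle.duct_mode == "multi":
        data = crop[None] if crop.ndim == 3 else crop
        padded, pads = _pad_to_patch(data, bundle.duct_tiling.patch_size)
        acc = None
        for m in duct_models:
            if m.config.out_channels != 3:
                raise ValueError("multi-label duct model must output 3 channels")
            pred = sliding_window_predict(m, padded, bundle.duct_tiling)
            acc = pred if acc is None else acc + pred
        acc /= len(duct_models)
        acc = _unpad(acc, pads, data.shape[1:])
        return acc[1], acc[2]  # channel order: background, CBD, PD
    cbd_models, pd_models = duct_models
    cbd_p = _fold_mean_sliding(cbd_models, crop, bundle.duct_tiling)
    pd_p = _fold_mean_sliding(pd_models, crop, bundle.duct_tiling)
    return cbd_p, pd_p


def filter_ducts_by_pancreas(duct_mask: np.ndarray, pancreas_mask: np.ndarray,
                             connectivity: int = 26, attach_radius: int = 2) -> np.ndarray:
    """Drop duct components that do not originate from the pancreas.

    A component is kept iff it intersects the pancreas mask dilated by
    ``attach_radius`` voxels.  Output is a subset of the input and the
    operation is idempotent.
    """
    duct_mask = np.asarray(duct_mask).astype(bool)
    pancreas_mask = np.asarray(pancreas_mask).astype(bool)
    if duct_mask.shape != pancreas_mask.shape:
        raise ValueError("duct and pancreas masks must share a shape")
    if not duct_mask.any():
        return np.zeros_like(duct_mask)
    if attach_radius > 0 and pancreas_mask.any():
        attach = ndi.binary_dilation(pancreas_mask, structure=_STRUCTS[connectivity],
                                     iterations=attach_radius)
    else:
        attach = pancreas_mask
    lab, n = ndi.label(duct_mask, structure=_STRUCTS[connectivity])
    keep_ids = np.unique(lab[attach & (lab > 0)])
    return np.isin(lab, keep_ids[keep_ids > 0])


def detect_tumor(crop: np.ndarray, pancreas_mask: np.ndarray, cbd_mask: np.ndarray,
                 pd_mask: np.ndarray, tumor_models, gt: LabelMap | None = None,
                 region: CropRegion | None = None, bundle: StageBundle | None = None,
                 include_ducts: bool = True) -> list[np.ndarray]:
    """Per-fold tumor probability grids from the secondary-feature input.

    Channel order of the stacked input is fixed: CT, pancreas, common bile
    duct, pancreatic duct.  The model sees the whole crop in one forward
    pass (large receptive field; no tiling).
    """
    if tumor_models == ORACLE:
        if gt is None or region is None or bundle is None:
            raise ValueError("oracle tumor stage requires ground truth and crop region")
        tm = _gt_structure(gt, "tumor", bundle.high_spacing)
        prob, _ = _extract_by_region(Volume(tm.astype(np.uint8), bundle.high_spacing), region)
        return [prob]
    channels = [crop, pancreas_mask.astype(float)]
    if include_ducts:
        channels += [cbd_mask.astype(float), pd_mask.astype(float)]
    x = np.stack(channels)
    grids = []
    for m in tumor_models:
        if m.config.in_channels != x.shape[0]:
            raise ValueError(
                f"tumor model expects {m.config.in_channels} channels, input has {x.shape[0]}"
            )
        grids.append(m.predict_proba(x)[0])
    return grids


def ensemble_and_classify(fold_grids: list[np.ndarray], threshold: float = 0.61):
    """Voxel-wise mean of fold grids, then max-voxel case score and call.

    The mean is taken before the max — the case score is the peak of the
    ensemble probability map, not the mean of per-fold peaks.
    """
    if not fold_grids:
        raise ValueError("need at least one fold grid")
    mean_grid = np.mean(np.stack(fold_grids), axis=0)
    per_fold = [float(g.max()) for g in fold_grids]
    score = float(mean_grid.max())
    return mean_grid, per_fold, score, bool(score >= threshold)


def patient_score(scan_scores, rule: str = "max") -> float:
    """Aggregate per-scan case scores into one patient-level score."""
    scores = list(scan_scores)
    if not scores:
        raise ValueError("patient_score needs at least one scan score")
    if rule == "max":
        return float(max(scores))
    if rule == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregation rule {rule!r}")


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(ct: Volume, bundle: StageBundle, gt: LabelMap | None = None,
                 case_id: str = "case", tumor_inputs: str = "predicted",
                 include_ducts: bool = True) -> DetectionResult:
    """Execute locate -> fine pancreas -> ducts -> filter -> tumor -> ensemble.

    ``tumor_inputs="gt"`` feeds ground-truth pancreas/duct masks to the
    tumor stage (the annotated-input condition); ``"predicted"`` feeds the
    upstream predictions.  A coarse-localization failure yields a negative
    call flagged ``pancreas_not_located`` rather than an exception.
    """
    high = ct if tuple(ct.spacing) == tuple(bundle.high_spacing) else resample(
        ct, bundle.high_spacing, mode="linear")
    try:
        center = locate_pancreas(ct, bundle.coarse_pancreas, bundle, gt=gt)
    except PancreasNotLocatedError:
        return DetectionResult(
            case_id=case_id, tumor_prob=np.zeros((1, 1, 1)), per_fold_scores=[],
            case_score=0.0, call=False, masks={}, crop_region=None,
            flags=["pancreas_not_located"],
        )
    pan_prob, region, crop = segment_pancreas_fine(high, center, bundle.fine_pancreas,
                                                   bundle, gt=gt)
    cbd_prob, pd_prob = segment_ducts(crop, bundle.ducts, bundle, gt=gt, region=region)

    pan_mask = binarize(pan_prob, bundle.mask_threshold)
    cbd_mask = filter_ducts_by_pancreas(binarize(cbd_prob, bundle.mask_threshold), pan_mask,
                                        bundle.connectivity, bundle.attach_radius)
    pd_mask = filter_ducts_by_pancreas(binarize(pd_prob, bundle.mask_threshold), pan_mask,
                                       bundle.connectivity, bundle.attach_radius)

    if tumor_inputs == "gt":
        if gt is None:
            raise ValueError("tumor_inputs='gt' requires ground truth")
        gpan = _gt_structure(gt, "pancreas", bundle.high_spacing)
        gcbd = _gt_structure(gt, "common_bile_duct", bundle.high_spacing)
        gpd = _gt_structure(gt, "pancreatic_duct", bundle.high_spacing)
        t_pan = _extract_by_region(Volume(gpan.astype(np.uint8), bundle.high_spacing), region)[0] > 0.5
        t_cbd = _extract_by_region(Volume(gcbd.astype(np.uint8), bundle.high_spacing), region)[0] > 0.5
        t_pd = _extract_by_region(Volume(gpd.astype(np.uint8), bundle.high_spacing), region)[0] > 0.5
    else:
        t_pan, t_cbd, t_pd = pan_mask, cbd_mask, pd_mask

    fold_grids = detect_tumor(crop, t_pan, t_cbd, t_pd, bundle.tumor, gt=gt,
                              region=region, bundle=bundle, include_ducts=include_ducts)
    tumor_prob, per_fold, score, call = ensemble_and_classify(fold_grids, bundle.threshold)
    tumor_mask = binarize(tumor_prob, bundle.threshold)

    masks = {"pancreas": pan_mask, "common_bile_duct": cbd_mask,
             "pancreatic_duct": pd_mask, "tumor": tumor_mask}
    result = DetectionResult(case_id=case_id, tumor_prob=tumor_prob,
                             per_fold_scores=per_fold, case_score=score, call=call,
                             masks=masks, crop_region=region)
    if gt is not None:
        from .evaluation import dice
        for name, mask in masks.items():
            gm = _gt_structure(gt, name, bundle.high_spacing)
            gm_crop = _extract_by_region(Volume(gm.astype(np.uint8), bundle.high_spacing), region)[0] > 0.5
            result.dscs[name] = dice(mask, gm_crop)
    return result
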