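"""Sliding-window tiling and probability aggregation.

Fixed-size patch models process arbitrary volumes by tiling with a stride
per axis; the final start on each axis is clamped so the last patch is
flush with the boundary and every voxel receives at least one prediction.
Overlapping patch predictions are merged by unweighted arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage as ndi

__all__ = ["TilingSpec", "tile_positions", "sliding_window_predict",
           "binarize", "largest_component"]


@dataclass(frozen=True)
class TilingSpec:
    patch_size: tuple[int, int, int]
    stride: tuple[int, int, int] = (32, 32, 32)

    def __post_init__(self) -> None:
        for a in range(3):
            if not (1 <= self.stride[a] <= self.patch_size[a]):
                raise ValueError(
                    f"stride must satisfy 1 <= stride <= patch_size on axis {a}, "
                    f"got stride {self.stride[a]} for patch {self.patch_size[a]}"
                )


def tile_positions(volume_shape, spec: TilingSpec) -> list[tuple[int, int, int]]:
    """All patch start indices covering the volume (cartesian over axes)."""
    per_axis = []
    for a in range(3):
        n, p, s = int(volume_shape[a]), spec.patch_size[a], spec.stride[a]
        if n < p:
            raise ValueError(
                f"volume extent {n} smaller than patch size {p} on axis {a}"
            )
        starts = list(range(0, n - p + 1, s))
        if starts[-1] != n - p:
            starts.append(n - p)  # clamp so the last patch is boundary-flush
        per_axis.append(starts)
    return [tuple(t) for t in product(*per_axis)]


def sliding_window_predict(model, volume: np.ndarray, spec: TilingSpec) -> np.ndarray:
    """Tile, predict each patch, average overlapping predictions per voxel.

    ``volume`` is channel-first ``(C, X, Y, Z)``; output is
    ``(out_channels, X, Y, Z)`` with every value in [0, 1].
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 3:
        volume = volume[None]
    shape = volume.shape[1:]
    positions = tile_positions(shape, spec)
    p = spec.patch_size
    out_c = model.config.out_channels
    acc = np.zeros((out_c,) + shape)
    cnt = np.zeros(shape)
    for (i, j, k) in positions:
        patch = volume[:, i:i + p[0], j:j + p[1], k:k + p[2]]
        pred = model.predict_proba(patch)
        acc[:, i:i + p[0], j:j + p[1], k:k + p[2]] += pred
        cnt[i:i + p[0], j:j + p[1], k:k + p[2]] += 1.0
    return acc / cnt[None]


def binarize(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a probability grid (inclusive: prob >= threshold)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return np.asarray(prob) >= threshold


_STRUCTS = {6: ndi.generate_binary_structure(3, 1),
            18: ndi.generate_binary_structure(3, 2),
            26: ndi.generate_binary_structure(3, 3)}


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component (empty in -> empty out).

    Size ties break toward the component containing the lexicographically
    smallest voxel, which is the lowest label id under scan-order labelling.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    lab, n = ndi.label(mask, structure=_STRUCTS[connectivity])
    sizes = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(sizes)) + 1  # argmax takes the first (smallest id) on ties
    return lab == best
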