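"""Volumetric image data model and geometry primitives.

A :class:`Volume` is a 3D scalar grid (axis order x, y, z — two in-plane
axes then the axial axis) with a voxel spacing in millimetres and a world
origin.  A :class:`LabelMap` is the matching integer grid naming anatomical
structures.  All cascade stages communicate through these carriers plus
:class:`CropRegion`, which ties a fixed-size crop back to its source grid.

Conventions: 0-based voxel indices, half-open boxes ``[start, start+size)``,
the world position of voxel ``(i,j,k)`` is ``origin + index * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Volume",
    "LabelMap",
    "CropRegion",
    "STRUCTURES",
    "load_volume",
    "save_volume",
    "load_labelmap",
    "save_labelmap",
    "resample",
    "normalize_hu",
    "extract_crop",
    "paste_crop",
    "map_index_between_spacings",
]

#: canonical structure names -> label integers used throughout the package
STRUCTURES = {"pancreas": 1, "pancreatic_duct": 2, "common_bile_duct": 3, "tumor": 4}

#: CT intensity window in Hounsfield units used for normalization
HU_WINDOW = (-87.0, 199.0)


@dataclass
class Volume:
    """3D scalar grid with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim} axes")
        if min(self.data.shape) < 1:
            raise ValueError("every Volume axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class LabelMap:
    """Integer grid aligned to a Volume; ``label_names`` maps int -> structure."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be an integer grid")
        if self.data.min() < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not named in label_names")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def mask(self, structure: str) -> np.ndarray:
        """Binary mask of one named structure (False everywhere if absent)."""
        ids = [i for i, n in self.label_names.items() if n == structure]
        if not ids:
            return np.zeros(self.data.shape, dtype=bool)
        return np.isin(self.data, ids)


@dataclass(frozen=True)
class CropRegion:
    """Half-open voxel box [start, start+size) into a source grid.

    ``start`` may be negative (the crop was padded); the box must intersect
    the source grid.
    """

    start: tuple[int, int, int]
    size: tuple[int, int, int]
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("CropRegion size components must be > 0")
        for a in range(3):
            lo = max(self.start[a], 0)
            hi = min(self.start[a] + self.size[a], self.source_shape[a])
            if hi <= lo:
                raise ValueError("CropRegion does not intersect the source grid")


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(float)
    aff[:3, 3] = origin
    return aff


def load_volume(path) -> Volume:
    """Load a 3D NIfTI image, reoriented to the canonical (RAS-like) axes.

    Spacing and origin are taken from the file's affine; intensities are
    returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D image, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    aff = img.affine
    if not np.isfinite(aff).all() or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValueError(f"non-invertible geometry in {path}")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in aff[:3, 3])
    return Volume(data=data, spacing=spacing, origin=origin)


def save_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine_from(v.spacing, v.origin))
    nib.save(img, str(path))


def save_labelmap(lm: LabelMap, path) -> None:
    """Write a label map as uint8 NIfTI plus a sidecar JSON naming labels."""
    img = nib.Nifti1Image(np.asarray(lm.data, dtype=np.uint8), _affine_from(lm.spacing, lm.origin))
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in lm.label_names.items()}))


def load_labelmap(path) -> LabelMap:
    v = load_volume(path)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".labels.json")
    if sidecar.exists():
        names = {int(k): n for k, n in json.loads(sidecar.read_text()).items()}
    else:
        names = {i: n for n, i in STRUCTURES.items()}
    return LabelMap(
        data=np.asarray(v.data).astype(np.int32),
        spacing=v.spacing,
        origin=v.origin,
        label_names=names,
    )


def _out_shape(shape, spacing, target_spacing) -> tuple[int, ...]:
    # round half up per axis, minimum 1 — deterministic across platforms
    return tuple(
        max(1, int(np.floor(n * s / t + 0.5)))
        for n, s, t in zip(shape, spacing, target_spacing)
    )


def resample(v: Volume, target_spacing, mode: str = "linear") -> Volume:
    """Resample to a new voxel spacing, preserving the world frame.

    ``mode`` is ``linear`` for intensities or ``nearest`` for label grids
    (nearest never invents new label values).  Output shape is
    ``round(shape * spacing / target_spacing)`` per axis, minimum 1.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    out_shape = _out_shape(v.shape, v.spacing, target_spacing)
    # sample at world positions of the output voxel centres, expressed in
    # input voxel index units: i_in = i_out * t / s
    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(out_shape, target_spacing, v.spacing)],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndi.map_coordinates(
        np.asarray(v.data, dtype=float if mode == "linear" else v.data.dtype),
        np.stack([g.ravel() for g in grids]),
        order=order,
        mode="nearest",
    ).reshape(out_shape)
    if mode == "nearest":
        out = out.astype(v.data.dtype)
    return Volume(data=out, spacing=target_spacing, origin=v.origin)


def normalize_hu(v: Volume, window=HU_WINDOW) -> Volume:
    """Clip to the HU window and scale affinely to [0, 1]."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"window must satisfy lo < hi, got ({lo}, {hi})")
    out = (np.clip(np.asarray(v.data, dtype=float), lo, hi) - lo) / (hi - lo)
    return v.with_data(out)


def extract_crop(v: Volume, center, size, fill: float = 0.0) -> tuple[Volume, CropRegion]:
    """Fixed-size crop centred on a voxel; out-of-bounds voxels take ``fill``.

    Returns the crop and a :class:`CropRegion` with
    ``start = center - size // 2`` (integer floor division per axis).
    """
    center = tuple(int(c) for c in center)
    size = tuple(int(s) for s in size)
    for a in range(3):
        if not (0 <= center[a] < v.shape[a]):
            raise ValueError(f"crop center {center} outside grid of shape {v.shape}")
    start = tuple(center[a] - size[a] // 2 for a in range(3))
    region = CropRegion(start=start, size=size, source_shape=v.shape)
    out = np.full(size, fill, dtype=float)
    src_lo = [max(start[a], 0) for a in range(3)]
    src_hi = [min(start[a] + size[a], v.shape[a]) for a in range(3)]
    dst_lo = [src_lo[a] - start[a] for a in range(3)]
    dst_hi = [dst_lo[a] + (src_hi[a] - src_lo[a]) for a in range(3)]
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = np.asarray(
        v.data
    )[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    new_origin = tuple(v.origin[a] + start[a] * v.spacing[a] for a in range(3))
    return Volume(data=out, spacing=v.spacing, origin=new_origin), region


def paste_crop(target_shape, crop: Volume, region: CropRegion, background: float = 0.0) -> np.ndarray:
    """Paste a crop back into a source-shaped grid; out-of-bounds voxels drop."""
    target_shape = tuple(int(n) for n in target_shape)
    if target_shape != tuple(region.source_shape):
        raise ValueError(
            f"target shape {target_shape} != region source shape {region.source_shape}"
        )
    if tuple(crop.shape) != tuple(region.size):
        raise ValueError(f"crop shape {crop.shape} != region size {region.size}")
    out = np.full(target_shape, background, dtype=float)
    start = region.start
    src_lo = [max(start[a], 0) for a in range(3)]
    src_hi = [min(start[a] + region.size[a], target_shape[a]) for a in range(3)]
    crop_lo = [src_lo[a] - start[a] for a in range(3)]
    crop_hi = [crop_lo[a] + (src_hi[a] - src_lo[a]) for a in range(3)]
    out[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]] = np.asarray(
        crop.data
    )[crop_lo[0]:crop_hi[0], crop_lo[1]:crop_hi[1], crop_lo[2]:crop_hi[2]]
    return out


def map_index_between_spacings(index, from_spacing, to_spacing, from_origin=(0, 0, 0), to_origin=(0, 0, 0)):
    """Carry a voxel index from one grid to the nearest voxel of another.

    World positions of input and output agree to within half a target voxel.
    """
    if any(s <= 0 for s in tuple(from_spacing) + tuple(to_spacing)):
        raise ValueError("spacings must be positive")
    world = [from_origin[a] + index[a] * from_spacing[a] for a in range(3)]
    return tuple(
        int(np.floor((world[a] - to_origin[a]) / to_spacing[a] + 0.5)) for a in range(3)
    )
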