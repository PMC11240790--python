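"""Synthetic abdominal CT phantom with pancreas, ducts and head tumors.

The phantom emulates the statistical structure the detection cascade relies
on, at desk scale: a curved ellipsoidal pancreas spanning the volume
laterally, a thin pancreatic duct along its axis, a common bile duct
descending into the head, and — in tumor cases — a sphere planted in the
head region whose attenuation class (hypo/iso/hyper) sets its contrast
against pancreatic tissue.  An obstructing tumor dilates both ducts
upstream of itself (tail-ward for the pancreatic duct, liver-ward for the
bile duct) and effaces the duct segment it engulfs, so iso-attenuating
tumors — invisible by intensity — remain detectable through duct
morphology alone.

All randomness flows from a single integer seed; generation is bit-exact
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_core import STRUCTURES, LabelMap, Volume, save_labelmap, save_volume

__all__ = ["PhantomParams", "PhantomCase", "generate_case", "generate_cohort", "save_case"]

#: HU offset of the tumor vs surrounding pancreas, by attenuation class
ATTENUATION_OFFSETS = {"hypo": -30.0, "iso": 0.0, "hyper": +30.0}

#: hypo/iso/hyper case counts follow the cohort composition 77/14/8 (of 99)
DEFAULT_CLASS_MIX = (77, 14, 8)


@dataclass
class PhantomParams:
    """Generation parameters for one synthetic case.

    Tissue means (HU) sit inside the (−87, 199) CT window with realistic
    ordering: duct fluid < soft-tissue background < pancreas parenchyma.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    has_tumor: bool = False
    tumor_radius_mm: float = 6.0
    tumor_attenuation_class: str = "hypo"
    duct_dilation_factor: float = 1.8
    noise_sd_hu: float = 10.0
    background_hu: float = 40.0
    pancreas_hu: float = 80.0
    duct_hu: float = 10.0
    duct_radius_mm: float = 2.0
    cbd_radius_mm: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_attenuation_class not in ATTENUATION_OFFSETS:
            raise ValueError(f"unknown attenuation class {self.tumor_attenuation_class!r}")
        if not self.has_tumor:
            # no obstruction -> no dilation
            self.duct_dilation_factor = 1.0
        if self.duct_dilation_factor < 1.0:
            raise ValueError("duct_dilation_factor must be >= 1")

    @property
    def tumor_hu_offset(self) -> float:
        return ATTENUATION_OFFSETS[self.tumor_attenuation_class]


@dataclass
class PhantomCase:
    ct: Volume
    labels: LabelMap
    params: PhantomParams
    case_id: str = "case"


def _paint_tube(dist2_accum: np.ndarray, grid_mm, points, radii) -> None:
    """Mark voxels within per-point radii of a polyline sample set."""
    gx, gy, gz = grid_mm
    for (px, py, pz), r in zip(points, radii):
        d2 = (gx - px) ** 2 + (gy - py) ** 2 + (gz - pz) ** 2
        np.minimum(dist2_accum, d2 - r * r, out=dist2_accum)


def generate_case(params: PhantomParams, case_id: str = "case") -> PhantomCase:
    """Render one phantom CT + ground-truth label map, bit-exact per seed."""
    shape = tuple(int(n) for n in params.shape)
    spacing = tuple(float(s) for s in params.spacing)
    extent = [shape[a] * spacing[a] for a in range(3)]
    rng = np.random.default_rng(params.seed)

    # --- pancreas centreline: gentle sinusoid spanning x, head at low x
    n_s = 48
    s = np.linspace(0.0, 1.0, n_s)
    x0, x1 = 0.14 * extent[0], 0.86 * extent[0]
    yc = 0.5 * extent[1] + rng.uniform(-1.5, 1.5)
    zc = 0.5 * extent[2] + rng.uniform(-1.5, 1.5)
    amp = 0.08 * extent[1] * rng.uniform(0.7, 1.3)
    cx = x0 + s * (x1 - x0)
    cy = yc + amp * np.sin(np.pi * s)
    cz = zc + 0.03 * extent[2] * np.sin(2 * np.pi * s)
    centreline = np.stack([cx, cy, cz], axis=1)

    # organ radius tapers head -> tail
    r_head = 0.15 * extent[0]
    r_tail = 0.55 * r_head
    pan_r = r_head + (r_tail - r_head) * s

    if params.has_tumor and params.tumor_radius_mm > 1.3 * r_head:
        raise ValueError(
            f"tumor radius {params.tumor_radius_mm} mm exceeds the head region "
            f"(max {1.3 * r_head:.1f} mm at this volume size)"
        )

    ax = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    grid = (gx, gy, gz)

    big = np.full(shape, np.inf)

    pan_d2 = big.copy()
    _paint_tube(pan_d2, grid, centreline, pan_r)
    pancreas = pan_d2 < 0

    # tumor in the head region (first quarter of the centreline)
    i_tum = int(0.12 * n_s)
    tumor = np.zeros(shape, dtype=bool)
    if params.has_tumor:
        tc = centreline[i_tum]
        tumor = (gx - tc[0]) ** 2 + (gy - tc[1]) ** 2 + (gz - tc[2]) ** 2 < params.tumor_radius_mm**2
        tumor &= pancreas  # tumor confined to the organ

    # pancreatic duct along the centreline; dilated tail-ward (upstream) of
    # an obstructing tumor, effaced from the tumor head-ward
    pd_r = np.full(n_s, params.duct_radius_mm)
    pd_lo = 0
    if params.has_tumor:
        pd_r[i_tum + 1 :] *= params.duct_dilation_factor
        pd_lo = i_tum  # duct not visible from papilla up to the obstruction
    pd_d2 = big.copy()
    _paint_tube(pd_d2, grid, centreline[pd_lo:], pd_r[pd_lo:])
    pduct = (pd_d2 < 0) & pancreas
    if params.has_tumor:
        pduct &= ~tumor  # ductal interruption inside the tumor

    # common bile duct: descends from the top of the volume into the head,
    # meeting the centreline at the papilla; dilated above an obstruction
    ampulla = centreline[max(i_tum - 1, 0)] if params.has_tumor else centreline[1]
    n_c = 32
    t = np.linspace(0.0, 1.0, n_c)
    top = np.array([ampulla[0] + 0.08 * extent[0], ampulla[1], 0.92 * extent[2]])
    cbd_pts = top[None, :] + t[:, None] * (ampulla - top)[None, :]
    cbd_r = np.full(n_c, params.cbd_radius_mm)
    # stop at the pancreatic duct's surface so the junction stays a clean
    # interface instead of an overlapping blob
    d_amp = np.linalg.norm(cbd_pts - ampulla, axis=1)
    near = d_amp < params.duct_radius_mm + 0.5
    cbd_hi = int(np.argmax(near)) if near.any() else n_c
    if params.has_tumor:
        cbd_r *= params.duct_dilation_factor
        # truncate the segment engulfed by the tumor
        tc = centreline[i_tum]
        d_t = np.linalg.norm(cbd_pts - tc, axis=1)
        inside = d_t < params.tumor_radius_mm
        if inside.any():
            cbd_hi = min(cbd_hi, int(np.argmax(inside)))
    cbd_d2 = big.copy()
    _paint_tube(cbd_d2, grid, cbd_pts[:cbd_hi], cbd_r[:cbd_hi])
    cbd = cbd_d2 < 0
    if params.has_tumor:
        cbd &= ~tumor

    # --- compose CT (HU) and labels; precedence tumor > ducts > pancreas
    ct = np.full(shape, params.background_hu)
    ct[pancreas] = params.pancreas_hu
    ct[cbd] = params.duct_hu
    ct[pduct] = params.duct_hu
    if params.has_tumor:
        ct[tumor] = params.pancreas_hu + params.tumor_hu_offset
    ct = ct + rng.normal(0.0, params.noise_sd_hu, size=shape)

    # label precedence tumor > pancreatic duct > bile duct > pancreas; the
    # PD is painted over the CBD so the duct junction never splits a label
    lab = np.zeros(shape, dtype=np.int32)
    lab[pancreas] = STRUCTURES["pancreas"]
    lab[cbd] = STRUCTURES["common_bile_duct"]
    lab[pduct] = STRUCTURES["pancreatic_duct"]
    lab[tumor] = STRUCTURES["tumor"]

    labels = LabelMap(
        data=lab,
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        label_names={i: n for n, i in STRUCTURES.items()},
    )
    vol = Volume(data=ct, spacing=spacing, origin=(0.0, 0.0, 0.0))
    return PhantomCase(ct=vol, labels=labels, params=params, case_id=case_id)


def _apportion(n: int, weights) -> list[int]:
    """Largest-remainder apportionment of n items over integer weights."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def generate_cohort(
    n_tumor: int,
    n_control: int,
    base: PhantomParams | None = None,
    class_mix=DEFAULT_CLASS_MIX,
    seed: int = 0,
    radius_jitter: float = 0.35,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate a labelled cohort plus its manifest.

    Attenuation classes are apportioned over tumor cases by largest
    remainder of ``class_mix``; per-case seeds and tumor radii derive
    deterministically from the cohort seed.  The manifest records case id,
    tumor presence, class, tumor diameter (mm) and per-case seed.
    """
    if n_tumor < 0 or n_control < 0:
        raise ValueError("case counts must be >= 0")
    base = base if base is not None else PhantomParams()
    counts = _apportion(n_tumor, class_mix)
    classes = (
        ["hypo"] * counts[0] + ["iso"] * counts[1] + ["hyper"] * counts[2] + [None] * n_control
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(classes))]
    jit_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cases, rows = [], []
    for i, (cls, cseed) in enumerate(zip(classes, child_seeds)):
        case_id = f"case_{i:04d}"
        if cls is None:
            p = replace(base, has_tumor=False, seed=cseed)
        else:
            r = base.tumor_radius_mm * (1.0 + radius_jitter * float(jit_rng.uniform(-1, 1)))
            p = replace(
                base,
                has_tumor=True,
                tumor_attenuation_class=cls,
                tumor_radius_mm=r,
                duct_dilation_factor=base.duct_dilation_factor
                if base.duct_dilation_factor > 1
                else 1.8,
                seed=cseed,
            )
        cases.append(generate_case(p, case_id=case_id))
        rows.append(
            {
                "case_id": case_id,
                "has_tumor": cls is not None,
                "attenuation_class": cls if cls else "",
                "diameter_mm": round(2 * p.tumor_radius_mm, 3) if cls else np.nan,
                "seed": cseed,
            }
        )
    return cases, pd.DataFrame(rows)


def save_case(case: PhantomCase, out_dir) -> None:
    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    save_volume(case.ct, out / "ct.nii.gz")
    save_labelmap(case.labels, out / "labels.nii.gz")
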