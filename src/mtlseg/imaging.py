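"""Volumetric data model, NIfTI I/O, and voxel-level utilities.

All geometry is expressed in world millimetres via the 4x4 voxel-to-world
affine so that neighbourhood radii (3/5/7 mm) are resolution independent.
Voxel indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Label codebook shared by the whole package.
LABEL_CODEBOOK = {0: "background", 1: "HP", 2: "AM", 3: "EC"}
STRUCTURES = ("HP", "AM", "EC")
STRUCTURE_CODES = {"HP": 1, "AM": 2, "EC": 3}

_MIN_SHAPE = 8


def _validate_geometry(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"non-3D image: got {data.ndim} dimensions")
    if any(s < _MIN_SHAPE for s in data.shape):
        raise ValueError(f"shape must be >= {_MIN_SHAPE} per axis, got {data.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("non-invertible affine")
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("spacing must be strictly positive on all axes")


@dataclass
class Volume3D:
    """A 3D scalar grid plus a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _validate_geometry(self.data, self.affine)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_geometry(self, other: "Volume3D | LabelVolume | BinaryMask") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class LabelVolume:
    """Integer label grid over the codebook {0: background, 1: HP, 2: AM, 3: EC}."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(np.asarray(data, dtype=float))
            if not np.allclose(rounded, data):
                raise ValueError("label data must be integer valued")
            data = rounded.astype(np.int16)
        self.data = data.astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _validate_geometry(self.data, self.affine)
        bad = set(np.unique(self.data)) - set(LABEL_CODEBOOK)
        if bad:
            raise ValueError(f"label values outside codebook: {sorted(bad)}")

    shape = Volume3D.shape
    spacing = Volume3D.spacing
    voxel_to_world = Volume3D.voxel_to_world
    world_to_voxel = Volume3D.world_to_voxel
    same_geometry = Volume3D.same_geometry

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def structure_mask(self, structure: str) -> np.ndarray:
        return self.data == STRUCTURE_CODES[structure]

    def structure_volume(self, structure: str) -> float:
        """Structure volume in mm^3 (voxel count times voxel volume)."""
        return float(self.structure_mask(structure).sum()) * self.voxel_volume


@dataclass
class BinaryMask:
    """Boolean grid sharing geometry with the volume it masks."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _validate_geometry(self.data, self.affine)

    shape = Volume3D.shape
    spacing = Volume3D.spacing
    voxel_to_world = Volume3D.voxel_to_world
    world_to_voxel = Volume3D.world_to_voxel
    same_geometry = Volume3D.same_geometry


def load_volume(path: str | Path) -> Volume3D | LabelVolume:
    """Load a NIfTI-1 file; integer dtypes load as LabelVolume, floats as Volume3D."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    affine = np.asarray(img.affine, dtype=float)
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data=data, affine=affine)
    return Volume3D(data=data.astype(np.float64), affine=affine)


def save_volume(vol: Volume3D | LabelVolume | BinaryMask, path: str | Path) -> None:
    """Write to NIfTI-1. Labels/masks are stored as int16, scalars as float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, (LabelVolume, BinaryMask)):
        data = np.asarray(vol.data).astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


def dilate_label(
    label: LabelVolume | BinaryMask, iterations: int
) -> BinaryMask:
    """Morphological dilation of the foreground with a 6-connected element.

    Each iteration grows the foreground by one 6-neighbourhood shell; the
    result is always a superset of the input foreground.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    fg = np.asarray(label.data) > 0
    if not fg.any():
        raise ValueError("empty foreground")
    out = ndimage.binary_dilation(fg, structure=_STRUCT_6, iterations=iterations)
    return BinaryMask(data=out, affine=label.affine)


def normalize_intensity(vol: Volume3D, mask: BinaryMask) -> Volume3D:
    """Z-score the volume using the within-mask mean and SD.

    Voxels outside the mask are transformed with the same affine map so the
    whole image stays on one intensity scale.
    """
    if not vol.same_geometry(mask):
        raise ValueError("mask geometry does not match volume")
    m = mask.data
    if m.sum() < 100:
        raise ValueError("mask must contain >= 100 foreground voxels")
    vals = vol.data[m]
    mu = vals.mean()
    sd = vals.std()
    if sd < 1e-12:
        raise ValueError("zero within-mask variance")
    return Volume3D(data=(vol.data - mu) / sd, affine=vol.affine)


def trilinear_sample(
    vol: Volume3D | LabelVolume, points: np.ndarray, fill: float = 0.0
) -> np.ndarray:
    """Trilinear interpolation of the volume at world-mm points.

    Out-of-grid points return ``fill``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox = vol.world_to_voxel(pts)
    return ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        vox.T,
        order=1,
        mode="constant",
        cval=fill,
    )


def mask_bbox_slices(
    mask: BinaryMask, margin_mm: float = 10.0
) -> tuple[slice, slice, slice]:
    """Bounding-box slices of the mask foreground, padded by margin_mm."""
    idx = np.argwhere(mask.data)
    if len(idx) == 0:
        raise ValueError("empty mask")
    pad = np.ceil(margin_mm / mask.spacing).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.data.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def crop_volume(vol, slices: tuple[slice, slice, slice]):
    """Crop to voxel slices; the affine keeps world coordinates consistent."""
    lo = np.array([s.start for s in slices], dtype=float)
    affine = vol.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ lo
    return type(vol)(data=np.ascontiguousarray(vol.data[slices]), affine=affine)


def sample_voxel_coords(
    data: np.ndarray, vox_coords: np.ndarray, fill: float = 0.0, order: int = 1
) -> np.ndarray:
    """map_coordinates helper over raw voxel coordinates (N,3)."""
    return ndimage.map_coordinates(
        np.asarray(data, dtype=float),
        np.atleast_2d(vox_coords).T,
        order=order,
        mode="constant",
        cval=fill,
    )
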