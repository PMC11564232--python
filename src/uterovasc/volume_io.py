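"""NIfTI I/O for Doppler voxel grids and placental masks, plus scan manifests.

Grids are 3D scalar fields of power-Doppler amplitude (arbitrary units, >= 0)
on an isotropic lattice; masks are {0,1} volumes of the same shape delimiting
the placental segment.  Only isotropic spacing is supported: the length and
thickness markers multiply voxel counts by a single voxel edge length, which
is meaningless on an anisotropic lattice, so anisotropic files are rejected
rather than silently resampled.

Axis order is the array's native (x, y, z) with 0-based indices; no RAS/LPS
reorientation is attempted, coordinates are internal to this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "PlacentalMask",
    "ScanRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "filter_by_quality",
    "read_manifest",
    "write_manifest",
]

#: Default voxel edge length (mm) when a phantom or test does not specify one.
DEFAULT_SPACING_MM = 0.5

_SPACING_RTOL = 1e-3


@dataclass
class VoxelGrid:
    """3D power-Doppler amplitude field on an isotropic voxel lattice."""

    values: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("VoxelGrid requires a 3D array with positive dimensions")
        if not np.isfinite(self.values).all():
            raise ValueError("VoxelGrid values must be finite")
        if (self.values < 0).any():
            raise ValueError("Doppler amplitudes must be >= 0")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PlacentalMask:
    """Binary placental-segment mask; same shape as its companion grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.include)
        if arr.ndim != 3:
            raise ValueError("PlacentalMask requires a 3D array")
        self.include = (arr > 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.include.shape

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class ScanRecord:
    """One ultrasound acquisition: subject, gestational age, quality, file refs.

    Image quality is scored 0 (optimal) to 3 (unusable); quality-3 scans are
    excluded from analysis by :func:`filter_by_quality`.
    """

    subject_id: str
    ga_days: int
    quality: int
    grid_path: str = ""
    mask_path: str = ""

    def __post_init__(self) -> None:
        if not 0 <= int(self.quality) <= 3:
            raise ValueError(f"quality must be in 0..3, got {self.quality}")


def _check_isotropic(zooms) -> float:
    zooms = np.asarray(zooms[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=_SPACING_RTOL):
        raise ValueError(
            f"anisotropic voxel spacing {tuple(zooms)} not supported; "
            "resample to an isotropic lattice first"
        )
    return float(zooms[0])


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a 3D NIfTI volume as a :class:`VoxelGrid`.

    Raises on missing files, non-3D images, and anisotropic spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
    spacing = _check_isotropic(img.header.get_zooms())
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(values=np.asarray(data, dtype=np.float64), spacing_mm=spacing, origin_mm=origin)


def write_volume(grid: VoxelGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a grid to NIfTI; integer dtypes round-trip bit-exactly."""
    path = Path(path)
    affine = np.diag([grid.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = grid.origin_mm
    data = np.asarray(grid.values, dtype=dtype)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((grid.spacing_mm,) * 3)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> PlacentalMask:
    grid = read_volume(path)
    return PlacentalMask(include=grid.values > 0)


def write_mask(mask: PlacentalMask, path: str | Path, spacing_mm: float = DEFAULT_SPACING_MM) -> Path:
    grid = VoxelGrid(values=mask.include.astype(np.float64), spacing_mm=spacing_mm)
    return write_volume(grid, path, dtype=np.uint8)


def filter_by_quality(records: list[ScanRecord], max_quality: int = 2) -> list[ScanRecord]:
    """Keep scans usable for analysis (quality <= 2), preserving order.

    Quality 3 means unusable and such scans are dropped.  Idempotent; raises
    if any record carries a score outside 0..3.
    """
    for r in records:
        if not 0 <= int(r.quality) <= 3:
            raise ValueError(f"quality outside 0..3 for subject {r.subject_id}")
    return [r for r in records if int(r.quality) <= max_quality]


MANIFEST_COLUMNS = ["subject_id", "ga_days", "quality", "grid_path", "mask_path"]


def read_manifest(path: str | Path) -> list[ScanRecord]:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            subject_id=str(row.subject_id),
            ga_days=int(row.ga_days),
            quality=int(row.quality),
            grid_path=str(row.grid_path),
            mask_path=str(row.mask_path),
        )
        for row in df.itertuples()
    ]


def write_manifest(records: list[ScanRecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "ga_days": r.ga_days,
                "quality": r.quality,
                "grid_path": r.grid_path,
                "mask_path": r.mask_path,
            }
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
    return Path(path)
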