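"""Volumes, lesion masks and gray-level quantization.

A :class:`Volume` is a 3D scalar grid (an ADC or DWI map) with voxel spacing
in millimetres; a :class:`VOIMask` is a congruent binary lesion mask.  All
texture matrices operate on a :class:`QuantizedVOI`, the masked voxels
discretized to integer gray levels ``1..n_bins`` with a fixed-bin-number
scheme.  Grids must match exactly: the lesion outline drawn on DWI is copied
voxel-for-voxel onto the ADC map, so no resampling is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, FormatError, GeometryError

__all__ = [
    "Volume",
    "VOIMask",
    "QuantizedVOI",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "window_normalize",
    "transfer_mask",
    "quantize",
]


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing in mm.

    The affine is carried opaquely so round-trips through NIfTI preserve
    orientation metadata; no world-coordinate arithmetic is done beyond
    spacing-aware volume in ml.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class VOIMask:
    """Binary lesion mask congruent with its volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got {arr.ndim}D")
        self.data = arr.astype(bool)
        if not self.data.any():
            raise FormatError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0


@dataclass
class QuantizedVOI:
    """Masked voxels discretized to integer gray levels ``1..n_bins``.

    ``levels`` is a full-grid int array: 0 outside the mask, 1..n_bins inside.
    """

    levels: np.ndarray
    n_bins: int
    mask: VOIMask = field(repr=False)

    def __post_init__(self) -> None:
        inside = self.levels[self.mask.data]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ConfigurationError("levels outside [1, n_bins]")

    @property
    def voxel_count(self) -> int:
        return self.mask.voxel_count

    @property
    def n_effective_levels(self) -> int:
        return int(np.unique(self.levels[self.mask.data]).size)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; raises :class:`FormatError` for non-3D images."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing, affine=img.affine)


def write_volume(vol: Volume, path: str | Path) -> None:
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VOIMask:
    vol = read_volume(path)
    return VOIMask(data=vol.data > 0.5, spacing=vol.spacing, affine=vol.affine)


def write_mask(mask: VOIMask, path: str | Path) -> None:
    affine = mask.affine if mask.affine is not None else np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def window_normalize(vol: Volume, width: float, level: float) -> Volume:
    """Map intensities to [0, 1] by display window width/level.

    ``out = clip((in - (level - width/2)) / width, 0, 1)``; monotone
    non-decreasing in the input.
    """
    if width <= 0:
        raise ConfigurationError(f"window width must be > 0, got {width}")
    lo = level - width / 2.0
    out = np.clip((vol.data - lo) / width, 0.0, 1.0)
    return Volume(data=out, spacing=vol.spacing, affine=vol.affine)


def transfer_mask(mask_on_dwi: VOIMask, adc: Volume) -> VOIMask:
    """Copy the DWI lesion outline onto the ADC grid (grids must match)."""
    if mask_on_dwi.shape != adc.shape:
        raise GeometryError(
            f"mask grid {mask_on_dwi.shape} != ADC grid {adc.shape}; resampling is not supported"
        )
    return VOIMask(data=mask_on_dwi.data.copy(), spacing=adc.spacing, affine=adc.affine)


def quantize(vol: Volume, mask: VOIMask, n_bins: int = 32) -> QuantizedVOI:
    """Discretize masked intensities to gray levels 1..n_bins.

    Fixed-bin-number scheme over the VOI range:
    ``level = min(n_bins, floor(n_bins*(x - min)/(max - min)) + 1)``;
    a constant VOI maps to level 1 everywhere.  The scheme is invariant to
    affine rescaling ``x -> a*x + b`` (a > 0) of the VOI intensities.
    """
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    if vol.shape != mask.shape:
        raise GeometryError(f"volume grid {vol.shape} != mask grid {mask.shape}")
    x = vol.data[mask.data]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        levels[mask.data] = 1
    else:
        lv = np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int32) + 1
        np.minimum(lv, n_bins, out=lv)
        levels[mask.data] = lv
    return QuantizedVOI(levels=levels, n_bins=n_bins, mask=mask)
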