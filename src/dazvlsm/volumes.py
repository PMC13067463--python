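"""Mask volumes on a shared template grid: NIfTI I/O, binarization, validation.

All analysis downstream assumes every mask lives on one common template grid
(same shape and affine). Registration/normalization to that template is a
preprocessing step outside this package; here we only read, binarize,
validate and write volumes.

Conventions (stated once, enforced everywhere): voxel indices are 0-based;
world coordinates come from the NIfTI affine; the template is assumed RAS+,
so "right" means larger world x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "MaskVolume",
    "FormatError",
    "GridMismatchError",
    "read_mask",
    "write_volume",
    "validate_cohort_grid",
]


class FormatError(ValueError):
    """Input file is not a readable 3D NIfTI volume."""


class GridMismatchError(ValueError):
    """Volumes expected on one shared grid disagree in shape or affine."""


#: absolute tolerance on affine entries when comparing grids; loose enough
#: for header round-off across writers, tight against real misregistration
AFFINE_ATOL = 1e-4


@dataclass
class GridSpec:
    """Geometry of a 3D template grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (i, j, k).
    affine : (4, 4) ndarray
        Voxel-to-world transform (homogeneous coordinates, mm).
    midline_plane : float
        World x-coordinate of the midsagittal plane (default 0, the MNI
        convention).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    midline_plane: float = 0.0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing along each axis in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out.squeeze()

    def matches(self, other: "GridSpec", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    @classmethod
    def default(cls, shape: tuple[int, int, int]) -> "GridSpec":
        """1 mm isotropic grid centered on the world origin (midline x=0)."""
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[:3, 3] = -(np.array(shape, dtype=float) - 1.0) / 2.0
        return cls(shape=shape, affine=affine, midline_plane=0.0)


@dataclass
class MaskVolume:
    """A binary 3D lesion or template mask on a :class:`GridSpec`."""

    grid: GridSpec
    data: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask '{self.label}': data shape {self.data.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask '{self.label}' is not binary (values {vals[:5]}...)")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def center_of_mass_world(self) -> np.ndarray:
        """World-mm center of mass of the lesioned voxels."""
        idx = np.argwhere(self.data > 0)
        if idx.size == 0:
            raise ValueError(f"mask '{self.label}' is empty")
        return np.atleast_1d(self.grid.voxel_to_world(idx.mean(axis=0)))


def _grid_from_img(img: nib.Nifti1Image) -> GridSpec:
    return GridSpec(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def read_mask(path: str | Path, binarize_threshold: float = 0.5, label: str | None = None) -> MaskVolume:
    """Read a NIfTI volume and binarize it at ``binarize_threshold``.

    Values ``>= binarize_threshold`` map to 1, others to 0; nearest-neighbor
    resampled integer masks pass through unchanged at the default 0.5.

    Raises
    ------
    FormatError
        If the file is not readable NIfTI or is not a 3D volume.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    squeezed = [s for s in img.shape[3:] if s != 1]
    if len(img.shape) > 3 and squeezed:
        raise FormatError(
            f"{path}: expected a 3D volume, got shape {img.shape} "
            "(4D time series are not masks)"
        )
    data = np.asanyarray(img.dataobj).reshape(img.shape[:3])
    if not np.isfinite(data).all():
        raise FormatError(f"{path}: volume contains non-finite values")
    binary = (data >= binarize_threshold).astype(np.uint8)
    if label is None:
        label = path.name.removesuffix(".gz").removesuffix(".nii")
    if binary.sum() == 0:
        warnings.warn(f"mask '{label}' is empty after thresholding", stacklevel=2)
    return MaskVolume(grid=_grid_from_img(img), data=binary, label=label)


def write_volume(
    volume: MaskVolume | np.ndarray,
    path: str | Path,
    grid: GridSpec | None = None,
) -> Path:
    """Write a mask (uint8) or a real-valued map (float32) as NIfTI-1.

    Pass either a :class:`MaskVolume`, or a 3D array together with the
    ``grid`` it lives on. Integer masks round-trip bit-exactly.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    if isinstance(volume, MaskVolume):
        data = volume.data.astype(np.uint8)
        grid = volume.grid
    else:
        if grid is None:
            raise ValueError("writing a bare array requires a GridSpec")
        data = np.asarray(volume)
        if data.shape != grid.shape:
            raise GridMismatchError(
                f"array shape {data.shape} != grid shape {grid.shape}"
            )
        if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
            data = data.astype(np.int32)
        else:
            data = data.astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, path)
    return path


def validate_cohort_grid(masks: list[MaskVolume]) -> GridSpec:
    """Check that all masks share one grid and return it.

    Order-invariant: every mask is compared against the first one; any
    mismatch raises :class:`GridMismatchError` naming the offending mask.
    """
    if not masks:
        raise ValueError("validate_cohort_grid requires a nonempty mask list")
    ref = masks[0].grid
    for m in masks[1:]:
        if not ref.matches(m.grid):
            raise GridMismatchError(
                f"mask '{m.label}' is not on the shared grid "
                f"(shape {m.grid.shape} vs {ref.shape}, or affine differs "
                f"beyond {AFFINE_ATOL})"
            )
    return ref
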