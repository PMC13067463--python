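"""Spatial operations on cohort masks.

Hemisphere mirroring, dural-attachment-zone (DAZ) extraction by intersection
with a dural template, lesion frequency maps, and 3D connected components.

The DAZ is the part of an extra-axial tumor mask that touches the dural
template (convexity/skull-base shell, falx, tentorium). It serves as a proxy
for the tumor's site of origin: restricting voxel-wise analysis to the DAZ
removes the volume-driven spatial spillover that whole-tumor masks carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volumes import GridSpec, GridMismatchError, MaskVolume

__all__ = [
    "DuralTemplate",
    "FrequencyMap",
    "DazExtraction",
    "DURAL_LABELS",
    "mirror_to_right",
    "extract_daz",
    "frequency_map",
    "connected_components",
    "connectivity_structure",
]

#: label meanings inside a DuralTemplate volume
DURAL_LABELS = {0: "background", 1: "shell", 2: "falx", 3: "tentorium"}


@dataclass
class DuralTemplate:
    """Labeled dural mask: 0 background, 1 convexity/skull-base shell,
    2 falx, 3 tentorium. Nonzero voxels form the dural domain."""

    grid: GridSpec
    data: np.ndarray = field(repr=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError("dural template data does not match its grid")
        labels = np.unique(self.data)
        if not np.isin(labels, (0, 1, 2, 3)).all():
            raise ValueError(f"dural labels must be in {{0,1,2,3}}, got {labels}")
        self.data = self.data.astype(np.uint8)

    @property
    def domain(self) -> np.ndarray:
        """Boolean array of all dural voxels (any nonzero label)."""
        return self.data > 0

    def dilated_domain(self, dilation_voxels: int) -> np.ndarray:
        """Dural domain dilated by ``dilation_voxels`` (26-connectivity).

        Memoized per dilation (cohort runs intersect every mask with the
        same dilated domain).
        """
        if dilation_voxels < 0:
            raise ValueError("dilation_voxels must be >= 0")
        cache = self.__dict__.setdefault("_dilated_cache", {})
        if dilation_voxels not in cache:
            dom = self.domain
            if dilation_voxels > 0:
                dom = ndimage.binary_dilation(
                    dom, structure=connectivity_structure(26), iterations=dilation_voxels
                )
            cache[dilation_voxels] = dom
        return cache[dilation_voxels]


@dataclass
class FrequencyMap:
    """Per-voxel lesion counts across a cohort of binary masks."""

    grid: GridSpec
    counts: np.ndarray = field(repr=False)
    n_patients: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.counts.min() < 0 or self.counts.max() > self.n_patients:
            raise ValueError("counts must lie in [0, n_patients]")


class DazExtraction(NamedTuple):
    daz: MaskVolume
    attached: bool


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def mirror_to_right(
    mask: MaskVolume,
    grid: GridSpec | None = None,
    midline_band_mm: float = 2.0,
) -> MaskVolume:
    """Flip a left-hemisphere mask onto the right hemisphere.

    The mask is flipped along the x axis (index i -> (X-1)-i) iff its center
    of mass lies more than ``midline_band_mm`` to the left of the grid's
    midsagittal plane. Masks whose center of mass sits inside the midline
    band (falcine / parasagittal lesions straddling the midline) are left
    unflipped; set ``midline_band_mm=0`` to flip anything strictly left of
    the midline. Voxel count is always preserved.
    """
    grid = grid or mask.grid
    if mask.n_voxels == 0:
        warnings.warn(f"mask '{mask.label}' is empty; nothing to mirror", stacklevel=2)
        return mask
    com_x = float(mask.center_of_mass_world()[0])
    if com_x < grid.midline_plane - midline_band_mm:
        return MaskVolume(grid=grid, data=mask.data[::-1, :, :].copy(), label=mask.label)
    return mask


def extract_daz(
    tumor: MaskVolume,
    dura: DuralTemplate,
    dilation_voxels: int = 1,
) -> DazExtraction:
    """Intersect a tumor mask with the (optionally dilated) dural template.

    ``dilation_voxels=0`` is the literal intersection; the default of 1
    tolerates ~1 voxel of registration/segmentation jitter so thin dural
    sheets are not missed. The result is always a subset of the tumor.

    Returns the DAZ mask and an ``attached`` flag; an empty intersection
    (tumor nowhere near the dura) yields ``attached=False`` and it is the
    caller's decision whether to exclude the patient.
    """
    if not tumor.grid.matches(dura.grid):
        raise GridMismatchError(
            f"tumor '{tumor.label}' and dural template are on different grids"
        )
    domain = dura.dilated_domain(dilation_voxels)
    data = (tumor.data.astype(bool) & domain).astype(np.uint8)
    attached = bool(data.any())
    if not attached:
        warnings.warn(
            f"tumor '{tumor.label}' does not touch the dural template "
            f"(dilation {dilation_voxels}); empty DAZ",
            stacklevel=2,
        )
    return DazExtraction(
        daz=MaskVolume(grid=tumor.grid, data=data, label=tumor.label),
        attached=attached,
    )


def frequency_map(masks: list[MaskVolume]) -> FrequencyMap:
    """Per-voxel count of masks covering each voxel.

    Conservation invariant: the counts sum to the total lesioned-voxel
    count over all masks.
    """
    if not masks:
        raise ValueError("frequency_map requires a nonempty mask list")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    return FrequencyMap(grid=grid, counts=counts, n_patients=len(masks))


def connected_components(
    binary_map: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a 3D binary map.

    Returns ``(labels, sizes)`` where ``labels`` assigns 1..k to foreground
    voxels (0 background) and ``sizes[i]`` is the voxel count of component
    ``i+1``. Labeling is deterministic (scipy raster order).
    """
    binary = np.asarray(binary_map).astype(bool)
    labels, k = ndimage.label(binary, structure=connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    return labels, sizes
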