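"""Labeled segmentation volumes, region atlases and binary ribbon masks.

The analysis consumes already-labeled 3D segmentation volumes (NIfTI-1,
integer labels, 0 = background), e.g. a FreeSurfer cortical parcellation
exported to NIfTI.  Regions are defined by a user-supplied mapping from
label id to (lobe, hemisphere); from that mapping the standard eleven
regions are derived: four lobes per hemisphere, the two hemispheres, and
the whole brain.  Surface reconstruction, skull stripping and the
parcellation itself are upstream concerns and out of scope here.

All geometry downstream is computed in voxel units; physical spacing is
carried along and used only by the morphometry module.  No resampling or
reorientation is ever performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "LOBES",
    "HEMISPHERES",
    "LabeledVolume",
    "RegionSpec",
    "BinaryMask",
    "EmptyRegionWarning",
    "load_label_volume",
    "load_atlas_map",
    "default_region_atlas",
    "extract_region_mask",
    "save_mask",
    "load_mask",
]

LOBES = ("frontal", "parietal", "temporal", "occipital")
HEMISPHERES = ("left", "right")

_HEMI_SHORT = {"left": "LH", "right": "RH"}
_HEMI_ALIASES = {
    "left": "left", "l": "left", "lh": "left",
    "right": "right", "r": "right", "rh": "right",
}


class EmptyRegionWarning(UserWarning):
    """A region's label set selects no voxels in the given volume."""


@dataclass(frozen=True, eq=False)
class LabeledVolume:
    """A 3D integer-labeled segmentation grid with voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.grid.ndim}D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError(f"labels must be integers, got dtype {self.grid.dtype}")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        """True when all three voxel edges are equal within 1e-6 relative tolerance."""
        s = np.asarray(self.spacing, dtype=float)
        return bool(np.all(np.abs(s - s[0]) <= 1e-6 * s[0]))

    def labels(self) -> np.ndarray:
        """Sorted array of distinct non-background labels present."""
        u = np.unique(self.grid)
        return u[u > 0]


@dataclass(frozen=True)
class RegionSpec:
    """A named region as a set of segmentation labels.

    kind is one of ``whole_brain``, ``hemisphere``, ``lobe``; the kind
    selects the box-counting scale range used for that region.
    """

    name: str
    kind: str
    hemisphere: str
    label_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in ("whole_brain", "hemisphere", "lobe"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.hemisphere not in ("left", "right", "both"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.kind == "whole_brain" and self.hemisphere != "both":
            raise ValueError("whole-brain region must span both hemispheres")
        if not self.label_ids:
            raise ValueError(f"region {self.name!r} has an empty label set")


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """A 3D boolean voxel set (e.g. one region's grey-matter ribbon)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.grid.ndim}D")
        if self.grid.dtype != bool:
            object.__setattr__(self, "grid", self.grid.astype(bool))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return not self.grid.any()

    @property
    def is_isotropic(self) -> bool:
        s = np.asarray(self.spacing, dtype=float)
        return bool(np.all(np.abs(s - s[0]) <= 1e-6 * s[0]))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) voxel indices of the foreground, inclusive."""
        if self.is_empty:
            raise ValueError("empty mask has no bounding box")
        idx = np.argwhere(self.grid)
        return idx.min(axis=0), idx.max(axis=0)


def load_label_volume(path: str | Path) -> LabeledVolume:
    """Read a NIfTI segmentation volume into a :class:`LabeledVolume`.

    Axis order and orientation follow the file's voxel order; no resampling.
    Floating-point data are accepted only when every voxel is exactly an
    integer (lossless cast).
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.isfinite(data)):
            raise TypeError(f"{path}: non-finite voxel values in dtype {data.dtype}")
        rounded = np.round(data)
        if not np.array_equal(rounded, data):
            raise TypeError(
                f"{path}: voxel data of dtype {data.dtype} are not integer-valued; "
                "a label volume is required"
            )
        data = rounded.astype(np.int32)
    else:
        data = data.astype(np.int32, copy=False)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledVolume(grid=data, spacing=spacing)  # type: ignore[arg-type]


def load_atlas_map(path: str | Path) -> dict[int, tuple[str, str]]:
    """Read a label→(lobe, hemisphere) mapping from JSON or YAML.

    Keys are integer labels (as strings), values are objects with ``lobe``
    and ``hemisphere`` fields, e.g. ``{"11": {"lobe": "frontal",
    "hemisphere": "left"}}``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: atlas file must be a mapping of label -> region")
    out: dict[int, tuple[str, str]] = {}
    for key, val in raw.items():
        label = int(key)
        lobe = str(val["lobe"]).lower()
        hemi = _HEMI_ALIASES.get(str(val["hemisphere"]).lower())
        if lobe not in LOBES:
            raise ValueError(f"{path}: label {label}: unknown lobe {val['lobe']!r}")
        if hemi is None:
            raise ValueError(
                f"{path}: label {label}: unknown hemisphere {val['hemisphere']!r}"
            )
        out[label] = (lobe, hemi)
    return out


def default_region_atlas(
    label_map: Mapping[int, tuple[str, str]],
) -> list[RegionSpec]:
    """Build the standard 11 regions from a label→(lobe, hemisphere) mapping.

    Returns 8 lobe regions (4 lobes x 2 hemispheres), the two hemispheres
    (each the exact union of its lobes) and the whole brain (union of all),
    in that order.  Every lobe/hemisphere cell must receive at least one
    label; an empty cell is rejected naming the missing region.
    """
    cells: dict[tuple[str, str], set[int]] = {
        (lobe, hemi): set() for lobe in LOBES for hemi in HEMISPHERES
    }
    for label, (lobe, hemi) in label_map.items():
        if lobe not in LOBES:
            raise ValueError(f"label {label}: unknown lobe {lobe!r}")
        hemi_norm = _HEMI_ALIASES.get(str(hemi).lower())
        if hemi_norm is None:
            raise ValueError(f"label {label}: unknown hemisphere {hemi!r}")
        if int(label) <= 0:
            raise ValueError(f"label {label}: labels must be positive integers")
        cells[(lobe, hemi_norm)].add(int(label))

    regions: list[RegionSpec] = []
    for hemi in HEMISPHERES:
        for lobe in LOBES:
            ids = cells[(lobe, hemi)]
            name = f"{lobe.capitalize()} {_HEMI_SHORT[hemi]}"
            if not ids:
                raise ValueError(f"no labels assigned to region {name!r}")
            regions.append(
                RegionSpec(name=name, kind="lobe", hemisphere=hemi,
                           label_ids=frozenset(ids))
            )
    # order: the 8 lobes (LH block then RH block), then LH, RH, WB
    regions.sort(key=lambda r: (r.hemisphere, LOBES.index(r.name.split()[0].lower())))
    for hemi in HEMISPHERES:
        ids = frozenset().union(*(cells[(lobe, hemi)] for lobe in LOBES))
        regions.append(
            RegionSpec(name=_HEMI_SHORT[hemi], kind="hemisphere",
                       hemisphere=hemi, label_ids=ids)
        )
    all_ids = frozenset(int(k) for k in label_map)
    regions.append(
        RegionSpec(name="WB", kind="whole_brain", hemisphere="both",
                   label_ids=all_ids)
    )
    return regions


def extract_region_mask(vol: LabeledVolume, region: RegionSpec) -> BinaryMask:
    """Binary mask that is true exactly where the volume's label belongs to the region."""
    grid = np.isin(vol.grid, sorted(region.label_ids))
    if not grid.any():
        warnings.warn(
            f"region {region.name!r}: no voxels carry labels {sorted(region.label_ids)}",
            EmptyRegionWarning,
            stacklevel=2,
        )
    return BinaryMask(grid=grid, spacing=vol.spacing)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/1 NIfTI volume with its spacing in the header."""
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI volume back into a :class:`BinaryMask`."""
    vol = load_label_volume(path)
    return BinaryMask(grid=vol.grid != 0, spacing=vol.spacing)
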