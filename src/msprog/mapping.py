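"""3D intersection of significant slices into a voxel map and NIfTI mask.

A significant slice fixes one coordinate (sagittal -> x, coronal -> y,
axial -> z); intersecting one slice from each projection therefore pins
down a complete voxel.  Two counting rules are provided because the
per-projection slice lists may contain repeats when one slice hosts
several significant classifiers: ``product_of_counts`` multiplies the
raw list lengths (the headline voxel count of the reference analysis),
``unique_voxels`` deduplicates first and is the natural rule for a
binary brain mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import ANALYSIS_RANGES, Volume

__all__ = ["VoxelMap", "intersect_slices", "export_mask", "voxel_table"]

COUNT_RULES = ("product_of_counts", "unique_voxels")


@dataclass
class VoxelMap:
    """Cartesian-product voxel set built from per-projection coordinates."""

    voxels: list[tuple[int, int, int]]
    count_rule: str
    grid_shape: tuple[int, int, int]
    n_voxels: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_voxels = len(self.voxels)

    @property
    def unique_voxels(self) -> list[tuple[int, int, int]]:
        return sorted(set(self.voxels))


def intersect_slices(
    sig_coronal,
    sig_sagittal,
    sig_axial,
    count_rule: str = "product_of_counts",
    grid_shape: tuple[int, int, int] = (91, 109, 91),
) -> VoxelMap:
    """Intersect significant slice coordinates across the three projections.

    Inputs are coordinate lists (coronal = y, sagittal = x, axial = z),
    possibly with repeats under ``product_of_counts``.  Voxels are (x, y,
    z) triples.  An empty list on any projection yields an empty map with
    a warning — no intersection is then possible.
    """
    if count_rule not in COUNT_RULES:
        raise ValueError(f"count_rule must be one of {COUNT_RULES}, got {count_rule!r}")
    cor = [int(c) for c in sig_coronal]
    sag = [int(c) for c in sig_sagittal]
    ax = [int(c) for c in sig_axial]
    if count_rule == "unique_voxels":
        cor, sag, ax = sorted(set(cor)), sorted(set(sag)), sorted(set(ax))
    if not (cor and sag and ax):
        warnings.warn(
            "at least one projection has no significant slices; the voxel map is empty",
            stacklevel=2,
        )
        return VoxelMap([], count_rule, tuple(grid_shape))
    for name, coords in (("coronal", cor), ("sagittal", sag), ("axial", ax)):
        lo, hi = ANALYSIS_RANGES[name]
        bad = [c for c in coords if not lo <= c <= hi]
        if bad:
            raise ValueError(f"{name} coordinates {bad} outside analysis range [{lo}, {hi}]")
    voxels = [(x, y, z) for x, y, z in itertools.product(sag, cor, ax)]
    return VoxelMap(voxels, count_rule, tuple(grid_shape))


def export_mask(voxel_map: VoxelMap, reference: Volume) -> nib.Nifti1Image:
    """Binary NIfTI mask on the reference volume's grid.

    The mask marks unique voxels (a voxel counted several times under
    ``product_of_counts`` is still a single location in the brain).
    """
    shape = reference.grid_shape
    offenders = [
        v for v in voxel_map.unique_voxels
        if not all(0 <= c < s for c, s in zip(v, shape))
    ]
    if offenders:
        raise ValueError(f"voxels outside the reference grid {shape}: {offenders[:10]}")
    mask = np.zeros(shape, dtype=np.uint8)
    for x, y, z in voxel_map.unique_voxels:
        mask[x, y, z] = 1
    return nib.Nifti1Image(mask, reference.affine)


def voxel_table(voxel_map: VoxelMap) -> pd.DataFrame:
    """Voxel list as a DataFrame with columns x, y, z."""
    return pd.DataFrame(voxel_map.voxels, columns=["x", "y", "z"])
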