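"""MNI-grid volumes, intensity normalization, slicing and slab assignment.

Volumes are assumed already registered to the 2 mm MNI space
(91 x 109 x 91 voxels).  Each volume is cut into 2D slices along the
three anatomical projections; a slice enters the analysis only if at
least 10% of its pixels are non-zero, and every analysis slice belongs
to one of four contiguous slabs per projection.  Printed slice
coordinates are 0-based voxel indices on the 2 mm grid, the only
standard grid consistent with the analysis ranges (x<=77, y<=95, z<=73).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MNI_GRID_SHAPE",
    "MNI_AFFINE_2MM",
    "PROJECTIONS",
    "PROJECTION_AXES",
    "ANALYSIS_RANGES",
    "SLAB_RANGES",
    "INCLUSION_MIN_FRACTION",
    "Volume",
    "SliceImage",
    "SlabDefinition",
    "slab_definitions",
    "assign_slab",
    "normalize_intensity",
    "slice_volume",
    "slice_counts",
    "export_slices",
]

#: Standard 2 mm MNI grid.
MNI_GRID_SHAPE = (91, 109, 91)

#: Voxel-to-mm affine of the 2 mm MNI template (radiological x-flip).
MNI_AFFINE_2MM = np.array(
    [
        [-2.0, 0.0, 0.0, 90.0],
        [0.0, 2.0, 0.0, -126.0],
        [0.0, 0.0, 2.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

PROJECTIONS = ("coronal", "sagittal", "axial")

#: Array axis perpendicular to each projection plane (x, y, z order).
PROJECTION_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

#: Inclusive coordinate range analysed per projection: 79 coronal,
#: 64 sagittal and 62 axial slices.
ANALYSIS_RANGES = {"coronal": (17, 95), "sagittal": (14, 77), "axial": (12, 73)}

#: Four contiguous slabs per projection (inclusive coordinate ranges).
SLAB_RANGES = {
    "coronal": ((17, 36), (37, 51), (52, 76), (77, 95)),
    "sagittal": ((14, 29), (30, 45), (46, 61), (62, 77)),
    "axial": ((12, 26), (27, 41), (42, 56), (57, 73)),
}

#: A slice is analysed when at least this fraction of its pixels is non-zero.
INCLUSION_MIN_FRACTION = 0.10

NORMALIZED_MAX = 255.0


@dataclass
class Volume:
    """One subject's 3D intensity array on the MNI grid."""

    intensities: np.ndarray
    affine: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"volume {self.subject_id!r}: expected a 3D array, "
                f"got shape {self.intensities.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.intensities.shape)

    @classmethod
    def from_nifti(cls, path: str | os.PathLike, subject_id: str | None = None) -> "Volume":
        img = nib.load(str(path))
        sid = subject_id or Path(path).name.split(".")[0]
        return cls(np.asanyarray(img.dataobj), img.affine, sid)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.intensities, dtype=np.float32), self.affine)


@dataclass
class SliceImage:
    """A single 2D slice cut from a volume.

    ``coordinate`` is the voxel index along the axis perpendicular to the
    projection plane.  ``slab`` is 1-4 inside the analysis range, None
    outside.  ``included`` records the 10% non-zero-pixel rule.
    """

    pixels: np.ndarray
    projection: str
    coordinate: int
    slab: int | None
    included: bool
    subject_id: str


@dataclass(frozen=True)
class SlabDefinition:
    projection: str
    slab_id: int
    coordinate_range: tuple[int, int]


def slab_definitions(projection: str) -> list[SlabDefinition]:
    """The four slab definitions of one projection, in slab order."""
    _check_projection(projection)
    return [
        SlabDefinition(projection, i + 1, rng)
        for i, rng in enumerate(SLAB_RANGES[projection])
    ]


def _check_projection(projection: str) -> None:
    if projection not in PROJECTIONS:
        raise ValueError(
            f"unknown projection {projection!r}; expected one of {PROJECTIONS}"
        )


def assign_slab(projection: str, coordinate: int) -> int:
    """Slab id (1-4) of an analysis coordinate.

    Raises ValueError for coordinates outside the projection's analysis
    range rather than silently returning no slab.
    """
    _check_projection(projection)
    lo, hi = ANALYSIS_RANGES[projection]
    if not lo <= coordinate <= hi:
        raise ValueError(
            f"{projection} coordinate {coordinate} outside analysis range "
            f"[{lo}, {hi}]"
        )
    for slab_id, (a, b) in enumerate(SLAB_RANGES[projection], start=1):
        if a <= coordinate <= b:
            return slab_id
    raise AssertionError("slab ranges do not cover the analysis range")  # pragma: no cover


def normalize_intensity(volume: Volume) -> Volume:
    """Linearly rescale intensities so the maximum equals 255.

    Zero maps to zero, so background voxels stay background and the 10%
    inclusion rule is unaffected.
    """
    arr = np.asarray(volume.intensities, dtype=float)
    if arr.min() < 0:
        raise ValueError(f"volume {volume.subject_id!r} has negative intensities")
    vmax = arr.max()
    if vmax == 0:
        raise ValueError(f"volume {volume.subject_id!r} is all zero; cannot normalize")
    return replace(volume, intensities=arr * (NORMALIZED_MAX / vmax))


def _extract_plane(intensities: np.ndarray, projection: str, coordinate: int) -> np.ndarray:
    axis = PROJECTION_AXES[projection]
    return np.take(intensities, coordinate, axis=axis)


def slice_volume(volume: Volume, projection: str) -> list[SliceImage]:
    """Cut a volume into the projection's analysis slices.

    Returns one :class:`SliceImage` per coordinate of the analysis range
    (79 coronal, 64 sagittal, 62 axial), with the inclusion flag and slab
    id populated.
    """
    _check_projection(projection)
    lo, hi = ANALYSIS_RANGES[projection]
    axis = PROJECTION_AXES[projection]
    n_along = volume.grid_shape[axis]
    if n_along <= hi:
        raise ValueError(
            f"grid shape {volume.grid_shape} has only {n_along} voxels along "
            f"the {projection} axis but the analysis range ends at {hi}"
        )
    slices = []
    for coord in range(lo, hi + 1):
        pixels = _extract_plane(volume.intensities, projection, coord)
        frac_nonzero = np.count_nonzero(pixels) / pixels.size
        slices.append(
            SliceImage(
                pixels=pixels,
                projection=projection,
                coordinate=coord,
                slab=assign_slab(projection, coord),
                included=frac_nonzero >= INCLUSION_MIN_FRACTION,
                subject_id=volume.subject_id,
            )
        )
    return slices


def slice_counts(projection: str) -> dict[int, int]:
    """Number of analysis coordinates per slab of a projection."""
    _check_projection(projection)
    return {
        i + 1: b - a + 1 for i, (a, b) in enumerate(SLAB_RANGES[projection])
    }


def _to_jpg(pixels: np.ndarray, path: Path, size: int = 224) -> None:
    # contrast-stretched 8-bit export, upsampled to the classifier input size
    from PIL import Image

    arr = np.asarray(pixels, dtype=float)
    span = arr.max() - arr.min()
    if span > 0:
        arr = (arr - arr.min()) / span
    img = Image.fromarray(np.uint8(np.round(arr * 255.0)))
    img = img.resize((size, size), Image.BILINEAR)
    img.save(path, format="JPEG")


def export_slices(
    slices: list[SliceImage],
    directory: str | os.PathLike,
    format: str = "array",
    included_only: bool = True,
) -> pd.DataFrame:
    """Write slices to disk and return a manifest table.

    ``format='array'`` writes lossless ``.npy`` files (the analysis path);
    ``format='jpg'`` writes 8-bit grayscale JPEGs upsampled to 224x224
    with contrast stretching, matching the input expected by image
    classification backbones.
    """
    if format not in ("array", "jpg"):
        raise ValueError(f"format must be 'array' or 'jpg', got {format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in slices:
        if included_only and not s.included:
            continue
        stem = f"{s.subject_id}_{s.projection}_{s.coordinate:03d}"
        path = directory / (stem + (".npy" if format == "array" else ".jpg"))
        if format == "array":
            np.save(path, np.asarray(s.pixels))
        else:
            _to_jpg(np.asarray(s.pixels), path)
        rows.append(
            {
                "subject_id": s.subject_id,
                "projection": s.projection,
                "coordinate": s.coordinate,
                "slab": s.slab,
                "included": s.included,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["subject_id", "projection", "coordinate", "slab", "included", "path"]
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
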