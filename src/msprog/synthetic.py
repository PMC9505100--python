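"""Synthetic MNI-grid cohorts with planted, region-confined class signal.

The generator emulates the structure of an MS disability-progression
imaging study at desk scale: brain-like volumes on the 2 mm MNI grid,
an EDSS pair per patient constructed so the baseline-dependent
progression rule reproduces a known truth label, and, for progressed
patients, a mean-intensity offset confined to configurable voxel boxes.
Ground truth (labels and signal boxes) is carried alongside so every
downstream stage can be validated against it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .labeling import label_table, progression_threshold
from .volume import MNI_AFFINE_2MM, MNI_GRID_SHAPE, Volume

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "ellipsoid_mask",
]

#: (x, y, z) inclusive voxel boxes; default is a single frontal box.
Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

DEFAULT_SIGNAL_REGIONS: tuple[Box, ...] = (((30, 60), (78, 92), (40, 60)),)

# Discrete baseline-EDSS distribution over the grid points covered by the
# progression rule (0; 1.0-5.0; 5.5-7.5), peaked near the clinical median 3.
_EDSS_BASELINES = np.array(
    [0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5]
)
_EDSS_WEIGHTS = np.array(
    [0.06, 0.05, 0.06, 0.08, 0.09, 0.11, 0.11, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.02, 0.02]
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference study design: 181 patients of whom 62
    (34%) progress, volumes on the 91x109x91 2 mm MNI grid.  Intensities
    are produced directly in normalized 0-255 units: background 0 outside
    the brain mask, mean 120 inside, Gaussian noise, plus ``effect_size``
    added inside every signal box for progressed patients.
    """

    n_patients: int = 181
    prevalence: float = 62 / 181
    grid_shape: tuple[int, int, int] = MNI_GRID_SHAPE
    signal_regions: tuple[Box, ...] = DEFAULT_SIGNAL_REGIONS
    effect_size: float = 25.0
    noise_sd: float = 15.0
    base_intensity: float = 120.0
    gradient: float = 0.4
    brain_mask_kind: str = "ellipsoid"
    brain_mask: np.ndarray | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.n_positive < 1:
            raise ValueError(
                f"round({self.n_patients} x {self.prevalence}) < 1: no positive class"
            )
        if self.n_positive >= self.n_patients:
            raise ValueError("prevalence leaves no negative class")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        for box in self.signal_regions:
            self._check_box(box)
        if self.brain_mask_kind not in ("ellipsoid", "template_like"):
            raise ValueError(
                f"brain_mask_kind must be 'ellipsoid' or 'template_like', "
                f"got {self.brain_mask_kind!r}"
            )
        if self.brain_mask_kind == "template_like":
            if self.brain_mask is None:
                raise ValueError("brain_mask_kind='template_like' requires a brain_mask array")
            if tuple(np.shape(self.brain_mask)) != self.grid_shape:
                raise ValueError("brain_mask shape does not match grid_shape")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def _check_box(self, box: Box) -> None:
        if len(box) != 3:
            raise ValueError(f"signal region {box!r} must have 3 coordinate ranges")
        for (lo, hi), size in zip(box, self.grid_shape):
            if not (0 <= lo <= hi < size):
                raise ValueError(
                    f"signal region {box!r} falls outside the grid {self.grid_shape}"
                )

    @property
    def n_positive(self) -> int:
        # round-half-up keeps e.g. 181 x 62/181 -> 62 exact
        return int(np.floor(self.n_patients * self.prevalence + 0.5))


@dataclass
class SyntheticCohort:
    """Generated volumes, patient table and the ground truth behind them."""

    volumes: list[Volume]
    patients: pd.DataFrame
    truth: dict

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.truth["labels"], index=self.truth["patient_ids"], name="label")


def ellipsoid_mask(grid_shape: tuple[int, int, int], fill: float = 0.95) -> np.ndarray:
    """Boolean ellipsoid inscribed in the grid (semi-axes = fill x half-extent)."""
    axes = [np.arange(s, dtype=float) for s in grid_shape]
    centers = [(s - 1) / 2.0 for s in grid_shape]
    radii = [max(c * fill, 0.5) for c in centers]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip((xx, yy, zz), centers, radii))
    return r2 <= 1.0


def _sample_edss_pairs(labels: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """EDSS (baseline, follow-up) pairs consistent with the given labels.

    Positives get an increment of threshold + {0, 0.5, 1.0}; negatives an
    increment strictly below their baseline's threshold (never below 0
    when the baseline is 0).
    """
    n = labels.size
    baselines = rng.choice(_EDSS_BASELINES, size=n, p=_EDSS_WEIGHTS)
    followups = np.empty(n)
    for i, (b, y) in enumerate(zip(baselines, labels)):
        thr = progression_threshold(b)
        if y == 1:
            followups[i] = b + thr + rng.choice([0.0, 0.5, 1.0])
        else:
            below = np.arange(-0.5, thr - 0.25, 0.5)  # {-0.5, 0, ..., thr-0.5}
            below = below[b + below >= 0]
            followups[i] = b + rng.choice(below)
    return baselines, followups


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi + 1) for lo, hi in box)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config.seed``.

    Exactly ``round(n_patients x prevalence)`` patients are positive.
    Volumes are zero outside the brain mask; positive-class volumes have
    the mean intensity inside each signal region raised by
    ``effect_size``.  EDSS pairs are constructed so re-deriving labels
    from them reproduces the truth labels.
    """
    rng = np.random.default_rng(config.seed)
    n, n_pos = config.n_patients, config.n_positive

    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    sites = [1 + (i % 2) for i in range(n)]
    baselines, followups = _sample_edss_pairs(labels, rng)
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "site": sites,
            "edss_baseline": baselines,
            "edss_followup": followups,
        }
    )
    derived = label_table(patients)["label"].to_numpy()
    if not np.array_equal(derived, labels):  # pragma: no cover - generator invariant
        raise AssertionError("EDSS sampling failed to reproduce truth labels")

    if config.brain_mask_kind == "ellipsoid":
        mask = ellipsoid_mask(config.grid_shape)
    else:
        mask = np.asarray(config.brain_mask, dtype=bool)

    # mild linear intensity ramp: breaks the ellipsoid's mirror symmetry so
    # slice location is decodable, as it is in real anatomy
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) - (s - 1) / 2.0 for s in config.grid_shape],
        indexing="ij",
    )
    ramp = config.gradient * sum(grids)

    # bright one-voxel rim (skull-fat-like) saturated at 255: pins every
    # subject's maximum so per-volume max-normalization cannot encode a
    # subject- or class-specific global scale
    from scipy.ndimage import binary_erosion

    rim = mask & ~binary_erosion(mask)

    volumes = []
    for pid, y in zip(ids, labels):
        arr = (
            config.base_intensity
            + ramp
            + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        )
        if y == 1 and config.effect_size != 0.0:
            for box in config.signal_regions:
                arr[_box_slices(box)] += config.effect_size
        np.clip(arr, 0.0, 255.0, out=arr)
        arr[rim] = 255.0
        arr[~mask] = 0.0
        volumes.append(Volume(arr.astype(np.float32), MNI_AFFINE_2MM.copy(), pid))

    truth = {
        "patient_ids": ids,
        "labels": labels.tolist(),
        "signal_regions": [list(map(list, box)) for box in config.signal_regions],
        "effect_size": config.effect_size,
        "seed": config.seed,
    }
    return SyntheticCohort(volumes=volumes, patients=patients, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> dict:
    """Write a cohort as NIfTI volumes + CSV patient table + JSON truth.

    Returns a manifest dict (also saved as ``manifest.json``); reading the
    files back reproduces the arrays exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol_paths = []
    for vol in cohort.volumes:
        path = directory / f"{vol.subject_id}.nii"
        nib.save(vol.to_nifti(), str(path))
        vol_paths.append(path.name)
    cohort.patients.to_csv(directory / "patients.csv", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    manifest = {
        "n_volumes": len(vol_paths),
        "volumes": vol_paths,
        "patients_csv": "patients.csv",
        "truth_json": "truth.json",
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory: str | os.PathLike) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    volumes = [
        Volume.from_nifti(directory / name) for name in manifest["volumes"]
    ]
    patients = pd.read_csv(directory / manifest["patients_csv"])
    with open(directory / manifest["truth_json"]) as fh:
        truth = json.load(fh)
    return SyntheticCohort(volumes=volumes, patients=patients, truth=truth)
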