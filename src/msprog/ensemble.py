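"""Replica splits, the two-step training protocol, and prediction tables.

The study design is an ensemble of 100 stratified 90/10 train/validation
replicas.  For each replica, projection and slab, a binary progression
discriminator is fine-tuned from a slab-location pre-trained state and
scored on every included slice of the slab for every validation patient.
Null discriminators repeat the procedure with training labels permuted
(class counts preserved, validation untouched), giving every real model
a ground-truth noise reference.

The default backbone is deliberately lightweight — downsample,
standardize, PCA (fitted on the slab-location task), logistic
regression — behind a pluggable fit/score interface, so the statistical
machinery runs at desk scale; heavier image backbones can be plugged in
through :class:`ClassifierSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .volume import PROJECTIONS, Volume, normalize_intensity, slice_volume

__all__ = [
    "ReplicaSplit",
    "ClassifierSpec",
    "LightweightBackbone",
    "SliceDataset",
    "build_slice_dataset",
    "make_replicas",
    "pretrain_location",
    "train_discriminator",
    "enumerate_design",
    "PREDICTION_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Schema of the long prediction table (one row per validation patient
#: per included slice per model).
PREDICTION_COLUMNS = [
    "replica",
    "projection",
    "slab",
    "coordinate",
    "patient_id",
    "true_label",
    "score",
    "model_kind",
]

_SEED_MODULUS = 2**31 - 1


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ReplicaSplit:
    """One stratified train/validation partition of the cohort."""

    replica_id: int
    train_ids: list[str]
    val_ids: list[str]
    seed: int


def replica_seed(master_seed: int, replica_id: int) -> int:
    """Deterministic per-replica seed: (master x 100003 + replica) mod 2^31-1."""
    return (int(master_seed) * 100003 + int(replica_id)) % _SEED_MODULUS


def make_replicas(
    patients: pd.DataFrame,
    n_replicas: int = 100,
    train_fraction: float = 0.90,
    seed: int = 0,
) -> list[ReplicaSplit]:
    """Build stratified train/validation replicas.

    Each replica draws round(train_fraction x class size) patients per
    class into training (round half up, i.e. the remainder goes to the
    training set) and the rest into validation.  Replicas overlap — the
    ensemble is a set of distinct but not independent resamples.  For a
    119/62 cohort at 0.9 this gives train 163 (107 neg / 56 pos) and
    validation 18 (12 neg / 6 pos) in every replica.
    """
    if "label" not in patients.columns:
        raise ValueError("patients table must carry a 'label' column")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    by_class = {
        y: patients.loc[patients["label"] == y, "patient_id"].to_numpy()
        for y in (0, 1)
    }
    for y, ids in by_class.items():
        n_train = _round_half_up(train_fraction * ids.size)
        if n_train < 1 or n_train >= ids.size:
            raise ValueError(
                f"class {y} has {ids.size} patients; cannot stratify a "
                f"{train_fraction:.0%} split with both sides non-empty"
            )
    splits = []
    for r in range(1, n_replicas + 1):
        s = replica_seed(seed, r)
        rng = np.random.default_rng(s)
        train: list[str] = []
        val: list[str] = []
        for y in (0, 1):
            ids = rng.permutation(by_class[y])
            n_train = _round_half_up(train_fraction * ids.size)
            train.extend(ids[:n_train])
            val.extend(ids[n_train:])
        splits.append(ReplicaSplit(r, sorted(train), sorted(val), s))
    return splits


@dataclass
class ClassifierSpec:
    """Configuration of the pluggable slice classifier.

    ``backbone='lightweight_default'`` builds the bundled
    :class:`LightweightBackbone`; a user plugin is any zero-argument
    ``factory`` returning an object with the same ``fit_location`` /
    ``make_discriminator`` surface.  ``init_seed=None`` re-initializes
    the classifier per replica from the replica seed; a fixed integer
    uses the same initialization everywhere.
    """

    backbone: str = "lightweight_default"
    downsample: tuple[int, int] = (8, 8)
    n_components: int = 16
    C: float = 1.0
    max_iter: int = 500
    pretrain_task: str = "slab_location"
    init_seed: int | None = None
    factory: Callable[[], "LightweightBackbone"] | None = field(default=None, repr=False)

    def build(self) -> "LightweightBackbone":
        if self.factory is not None:
            return self.factory()
        if self.backbone != "lightweight_default":
            raise ValueError(
                f"unknown backbone {self.backbone!r}; supply a factory for plugins"
            )
        return LightweightBackbone(
            downsample=self.downsample,
            n_components=self.n_components,
            C=self.C,
            max_iter=self.max_iter,
        )


class LightweightBackbone:
    """Downsample -> standardize -> PCA -> logistic regression stack.

    ``fit_location`` performs the first training step (assigning slices
    to their slab); the representation it learns (scaler + PCA) is
    frozen and reused by every progression discriminator spawned with
    :meth:`make_discriminator`, mirroring a transfer-learning warm
    start.
    """

    def __init__(self, downsample=(8, 8), n_components=16, C=1.0, max_iter=500):
        self.downsample = tuple(downsample)
        self.n_components = int(n_components)
        self.C = float(C)
        self.max_iter = int(max_iter)
        self._scaler: StandardScaler | None = None
        self._pca: PCA | None = None
        self.location_model_: LogisticRegression | None = None
        self.location_accuracy_: float | None = None

    # -- feature layers -------------------------------------------------
    def extract(self, images: np.ndarray) -> np.ndarray:
        """Downsampled, flattened pixel features.

        Accepts a stack of 2D images ``(n, H, W)``; 2D input is taken to
        be an already-extracted feature matrix and passed through.
        """
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            return images
        if images.ndim != 3:
            raise ValueError("expected (n, H, W) image stack")
        out = np.empty((images.shape[0], int(np.prod(self.downsample))))
        for i, img in enumerate(images):
            out[i] = resize(
                img, self.downsample, anti_aliasing=True, preserve_range=True
            ).ravel()
        return out

    @property
    def pretrained(self) -> bool:
        return self._pca is not None

    def transform(self, images: np.ndarray) -> np.ndarray:
        x = self.extract(images)
        if self.pretrained:
            return self._pca.transform(self._scaler.transform(x))
        return x

    # -- step 1: slab-location pre-training -----------------------------
    def fit_location(
        self,
        images: np.ndarray,
        slab_labels: np.ndarray,
        holdout_fraction: float = 0.10,
        seed: int = 0,
    ) -> float:
        """Fit the 4-class location model; returns held-out accuracy."""
        x = self.extract(images)
        y = np.asarray(slab_labels)
        x_tr, x_ho, y_tr, y_ho = train_test_split(
            x, y, test_size=holdout_fraction, stratify=y, random_state=seed % _SEED_MODULUS
        )
        self._scaler = StandardScaler().fit(x_tr)
        n_comp = min(self.n_components, x_tr.shape[0] - 1, x_tr.shape[1])
        self._pca = PCA(n_components=n_comp, random_state=seed % _SEED_MODULUS)
        z_tr = self._pca.fit_transform(self._scaler.transform(x_tr))
        self.location_model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter
        ).fit(z_tr, y_tr)
        z_ho = self._pca.transform(self._scaler.transform(x_ho))
        self.location_accuracy_ = float(self.location_model_.score(z_ho, y_ho))
        return self.location_accuracy_

    # -- step 2: progression discriminators -----------------------------
    def make_discriminator(self, seed: int = 0) -> "ProgressionDiscriminator":
        return ProgressionDiscriminator(self, seed)


class ProgressionDiscriminator:
    """Binary progression classifier warm-started from the backbone.

    Exposes the plugin contract: ``fit(images, labels)`` and
    ``score(images) -> values in [0, 1]`` (higher = more likely to
    progress).
    """

    def __init__(self, backbone: LightweightBackbone, seed: int = 0):
        self.backbone = backbone
        self.seed = int(seed) % _SEED_MODULUS
        self._own_scaler: StandardScaler | None = None
        self._clf: LogisticRegression | None = None

    def _features(self, images: np.ndarray, fit: bool = False) -> np.ndarray:
        if self.backbone.pretrained:
            return self.backbone.transform(images)
        x = self.backbone.extract(images)
        if fit:
            self._own_scaler = StandardScaler().fit(x)
        if self._own_scaler is None:
            raise RuntimeError("discriminator not fitted")
        return self._own_scaler.transform(x)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "ProgressionDiscriminator":
        x = self._features(images, fit=True)
        self._clf = LogisticRegression(
            C=self.backbone.C, max_iter=self.backbone.max_iter, random_state=self.seed
        ).fit(x, np.asarray(labels))
        return self

    def score(self, images: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("discriminator not fitted")
        return self._clf.predict_proba(self._features(images))[:, 1]


@dataclass
class SliceDataset:
    """All included slices of one projection, stacked across the cohort.

    ``pixels`` has shape (n_coordinates, n_patients, H, W); a coordinate
    is kept only when its slice passes the 10% inclusion rule for every
    subject, so the tensor is dense.
    """

    projection: str
    patient_ids: list[str]
    labels: np.ndarray
    coordinates: np.ndarray
    slabs: np.ndarray
    pixels: np.ndarray
    _feature_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def coords_of_slab(self, slab_id: int) -> np.ndarray:
        return np.flatnonzero(self.slabs == slab_id)

    def features(self, backbone: LightweightBackbone) -> np.ndarray:
        """(n_coords, n_patients, d) downsampled features, cached."""
        key = backbone.downsample
        if key not in self._feature_cache:
            n_c, n_p = self.pixels.shape[:2]
            flat = backbone.extract(self.pixels.reshape((n_c * n_p,) + self.pixels.shape[2:]))
            self._feature_cache[key] = flat.reshape(n_c, n_p, -1)
        return self._feature_cache[key]

    def patient_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {pid: i for i, pid in enumerate(self.patient_ids)}
        missing = [p for p in ids if p not in lookup]
        if missing:
            raise ValueError(f"patients not in dataset: {missing[:5]}")
        return np.array([lookup[p] for p in ids])


def build_slice_dataset(
    volumes: Sequence[Volume],
    labels: pd.Series,
    projection: str,
    normalize: bool = True,
) -> SliceDataset:
    """Slice every volume along one projection into a dense dataset.

    ``labels`` maps subject id -> binary progression label.  Volumes are
    max-normalized to 255 first (disable for pre-normalized data).
    """
    patient_ids = [v.subject_id for v in volumes]
    missing = [p for p in patient_ids if p not in labels.index]
    if missing:
        raise ValueError(f"labels missing for subjects {missing[:5]}")
    per_subject = []
    for vol in volumes:
        v = normalize_intensity(vol) if normalize else vol
        per_subject.append(slice_volume(v, projection))
    coords = np.array([s.coordinate for s in per_subject[0]])
    slabs = np.array([s.slab for s in per_subject[0]])
    included = np.all(
        [[s.included for s in subject] for subject in per_subject], axis=0
    )
    keep = np.flatnonzero(included)
    if keep.size == 0:
        raise ValueError(f"no {projection} slice passes the inclusion rule for all subjects")
    pixels = np.stack(
        [np.stack([subject[i].pixels for subject in per_subject]) for i in keep]
    ).astype(np.float32)
    return SliceDataset(
        projection=projection,
        patient_ids=patient_ids,
        labels=np.array([int(labels[p]) for p in patient_ids]),
        coordinates=coords[keep],
        slabs=slabs[keep],
        pixels=pixels,
    )


def pretrain_location(
    backbone: LightweightBackbone,
    dataset: SliceDataset,
    seed: int = 0,
) -> float:
    """First training step: classify slices into their slab (unlabeled task).

    Uses every included slice of every subject; raises if any of the
    four slabs contributes no slices.  Returns held-out accuracy.
    """
    present = set(int(s) for s in dataset.slabs)
    missing = sorted(set(range(1, 5)) - present)
    if missing:
        raise ValueError(
            f"{dataset.projection}: slabs {missing} have no included slices; "
            "cannot pre-train the location task"
        )
    feats = dataset.features(backbone)
    n_c, n_p, d = feats.shape
    x = feats.reshape(n_c * n_p, d)
    y = np.repeat(dataset.slabs, n_p)
    acc = backbone.fit_location(x, y, seed=seed)
    logger.info("%s location pre-training accuracy: %.3f", dataset.projection, acc)
    return acc


def _permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # class counts preserved by construction: a pure permutation
    return rng.permutation(labels)


def train_discriminator(
    backbone: LightweightBackbone,
    dataset: SliceDataset,
    split: ReplicaSplit,
    slab_id: int,
    shuffle_labels: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fine-tune one slab discriminator and score the validation slices.

    Training instances are every included slice of the slab for every
    training patient, labeled with the patient's progression label (a
    permutation of those labels for null models; the validation set is
    never touched).  Returns prediction rows per ``PREDICTION_COLUMNS``.
    """
    coord_idx = dataset.coords_of_slab(slab_id)
    if coord_idx.size == 0:
        raise ValueError(f"slab {slab_id} of {dataset.projection} has no included slices")
    seed = split.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    feats = dataset.features(backbone)
    tr_idx = dataset.patient_index(split.train_ids)
    va_idx = dataset.patient_index(split.val_ids)
    y_train = dataset.labels[tr_idx]
    if shuffle_labels:
        y_train = _permute_labels(y_train, rng)

    n_c, d = coord_idx.size, feats.shape[2]
    x_train = feats[np.ix_(coord_idx, tr_idx)].reshape(n_c * tr_idx.size, d)
    y_rep = np.tile(y_train, n_c)
    disc = backbone.make_discriminator(seed=seed).fit(x_train, y_rep)

    x_val = feats[np.ix_(coord_idx, va_idx)].reshape(n_c * va_idx.size, d)
    scores = disc.score(x_val).reshape(n_c, va_idx.size)

    rows = {
        "replica": split.replica_id,
        "projection": dataset.projection,
        "slab": slab_id,
        "coordinate": np.repeat(dataset.coordinates[coord_idx], va_idx.size),
        "patient_id": np.tile(np.array(split.val_ids), n_c),
        "true_label": np.tile(dataset.labels[va_idx], n_c),
        "score": scores.ravel(),
        "model_kind": "null" if shuffle_labels else "real",
    }
    return pd.DataFrame(rows)[PREDICTION_COLUMNS]


def enumerate_design(
    n_replicas: int = 100,
    projections: Sequence[str] = PROJECTIONS,
    n_slabs: int = 4,
) -> pd.DataFrame:
    """Enumerate the discriminator design (replica x projection x slab).

    The full reference design (100 replicas, 3 projections, 4 slabs)
    enumerates 1200 binary discriminators.
    """
    rows = [
        {"replica": r, "projection": p, "slab": s}
        for r in range(1, n_replicas + 1)
        for p in projections
        for s in range(1, n_slabs + 1)
    ]
    return pd.DataFrame(rows)
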