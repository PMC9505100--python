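"""Model/Results objects orchestrating the whole slice-ensemble analysis.

:class:`SliceEnsembleModel` holds the data (volumes + patient table) and
the design (replicas, projections, classifier, thresholds);
:meth:`SliceEnsembleModel.fit` runs labeling, slicing, the two-step
ensemble training with matched permutation nulls, ROC/AUC statistics,
DeLong selection and voxel intersection, and returns a
:class:`SliceEnsembleResults` carrying every table plus ``summary()``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    ClassifierSpec,
    ReplicaSplit,
    build_slice_dataset,
    enumerate_design,
    make_replicas,
    pretrain_location,
    replica_seed,
    train_discriminator,
)
from .labeling import label_table
from .mapping import VoxelMap, export_mask, intersect_slices, voxel_table
from .roc import auc_table, summarize_distribution
from .selection import Z_CRITICAL, build_selection_table, select_significant
from .synthetic import GeneratorConfig, generate_cohort, read_cohort
from .volume import PROJECTIONS, Volume

__all__ = ["SliceEnsembleModel", "SliceEnsembleResults"]

logger = logging.getLogger(__name__)


class SliceEnsembleModel:
    """Slice-ensemble model of disability progression from MNI volumes.

    Parameters
    ----------
    volumes : sequence of Volume
        MNI-registered subject volumes (normalized internally).
    patients : DataFrame
        Patient table with ``patient_id`` and either a ``label`` column
        or the ``edss_baseline`` / ``edss_followup`` pair from which the
        progression label is derived.
    n_replicas : int
        Number of stratified train/validation replicas (study design:
        100; must be >= 4 so replica quartiles are defined).
    train_fraction : float
        Training share of each replica (study design: 0.90).
    projections : sequence of {'coronal', 'sagittal', 'axial'}
        Projections to analyse; the voxel map needs all three.
    classifier : ClassifierSpec, optional
        Backbone configuration; defaults to the lightweight stack.
    z_crit : float
        DeLong selection threshold (study design: 1.96).
    delta : float, optional
        Override of the null-admissibility half-width; default is the
        per-unit ROC granularity 1/(n_pos x n_neg).
    seed : int
        Master seed; every replica/classifier seed derives from it.
    """

    def __init__(
        self,
        volumes: Sequence[Volume],
        patients: pd.DataFrame,
        n_replicas: int = 100,
        train_fraction: float = 0.90,
        projections: Sequence[str] = PROJECTIONS,
        classifier: ClassifierSpec | None = None,
        z_crit: float = Z_CRITICAL,
        delta: float | None = None,
        seed: int = 0,
    ):
        if n_replicas < 4:
            raise ValueError("n_replicas must be >= 4 (replica quartiles undefined below)")
        if z_crit <= 0:
            raise ValueError("z_crit must be positive")
        if delta is not None and delta <= 0:
            raise ValueError("delta must be positive when given")
        unknown = set(projections) - set(PROJECTIONS)
        if unknown:
            raise ValueError(f"unknown projections {sorted(unknown)}")
        if "label" not in patients.columns:
            patients = label_table(patients)
        ids = set(patients["patient_id"])
        missing = [v.subject_id for v in volumes if v.subject_id not in ids]
        if missing:
            raise ValueError(f"volumes without patient rows: {missing[:5]}")
        self.volumes = list(volumes)
        self.patients = patients.reset_index(drop=True)
        self.n_replicas = int(n_replicas)
        self.train_fraction = float(train_fraction)
        self.projections = tuple(projections)
        self.classifier = classifier or ClassifierSpec()
        self.z_crit = float(z_crit)
        self.delta = delta
        self.seed = int(seed)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_synthetic(cls, config: GeneratorConfig | None = None, **kwargs) -> "SliceEnsembleModel":
        """Build the model from a freshly generated synthetic cohort."""
        cohort = generate_cohort(config or GeneratorConfig())
        return cls(cohort.volumes, cohort.patients, **kwargs)

    @classmethod
    def from_directory(cls, directory, **kwargs) -> "SliceEnsembleModel":
        """Build the model from a cohort directory (NIfTI volumes + patients.csv)."""
        directory = Path(directory)
        if (directory / "manifest.json").exists():
            cohort = read_cohort(directory)
            return cls(cohort.volumes, cohort.patients, **kwargs)
        patients = pd.read_csv(directory / "patients.csv")
        volumes = [
            Volume.from_nifti(p)
            for p in sorted(directory.glob("*.nii")) + sorted(directory.glob("*.nii.gz"))
        ]
        return cls(volumes, patients, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, verbose: bool = False) -> "SliceEnsembleResults":
        """Run the full analysis; deterministic for a fixed master seed."""
        labels = self.patients.set_index("patient_id")["label"]
        replicas = make_replicas(
            self.patients, self.n_replicas, self.train_fraction, self.seed
        )
        predictions = []
        location_accuracy: dict[str, float | None] = {}
        datasets = {}
        for k, projection in enumerate(self.projections):
            t0 = time.perf_counter()
            dataset = build_slice_dataset(self.volumes, labels, projection)
            datasets[projection] = dataset
            backbone = self.classifier.build()
            if self.classifier.pretrain_task == "slab_location":
                location_accuracy[projection] = pretrain_location(
                    backbone, dataset, seed=replica_seed(self.seed, 90_000 + k)
                )
            else:
                location_accuracy[projection] = None
            for split in replicas:
                init = self.classifier.init_seed
                real_seed = split.seed if init is None else init
                null_seed = split.seed + 1 if init is None else init
                for slab_id in sorted(set(int(s) for s in dataset.slabs)):
                    predictions.append(
                        train_discriminator(
                            backbone, dataset, split, slab_id,
                            shuffle_labels=False, seed=real_seed,
                        )
                    )
                    predictions.append(
                        train_discriminator(
                            backbone, dataset, split, slab_id,
                            shuffle_labels=True, seed=null_seed,
                        )
                    )
                if verbose:
                    logger.info(
                        "%s replica %d/%d done", projection, split.replica_id, len(replicas)
                    )
            logger.info(
                "projection %s: %.1fs", projection, time.perf_counter() - t0
            )
        predictions = pd.concat(predictions, ignore_index=True)
        auc_slices = auc_table(predictions, folded=False)
        auc_slabs = auc_table(predictions, folded=True)
        selection = build_selection_table(predictions, z_crit=self.z_crit, delta=self.delta)
        return SliceEnsembleResults(
            model=self,
            replicas=replicas,
            predictions=predictions,
            auc_slices=auc_slices,
            auc_slabs=auc_slabs,
            selection=selection,
            location_accuracy=location_accuracy,
            datasets=datasets,
        )


class SliceEnsembleResults:
    """Fitted results: prediction, AUC and selection tables plus maps."""

    def __init__(
        self,
        model: SliceEnsembleModel,
        replicas: list[ReplicaSplit],
        predictions: pd.DataFrame,
        auc_slices: pd.DataFrame,
        auc_slabs: pd.DataFrame,
        selection: pd.DataFrame,
        location_accuracy: dict,
        datasets: dict,
    ):
        self.model = model
        self.replicas = replicas
        self.predictions = predictions
        self.auc_slices = auc_slices
        self.auc_slabs = auc_slabs
        self.selection = selection
        self.location_accuracy = location_accuracy
        self.datasets = datasets
        self.selection_summary = select_significant(selection)

    # -- derived quantities ----------------------------------------------
    def significant_slices(self, projection: str) -> list[int]:
        """Selected slice coordinates (one entry per slice-classifier pair)."""
        return self.selection_summary["significant_slices"].get(projection, [])

    def voxel_map(self, count_rule: str = "product_of_counts") -> VoxelMap:
        """Intersect the per-projection significant slices into voxels."""
        return intersect_slices(
            self.significant_slices("coronal"),
            self.significant_slices("sagittal"),
            self.significant_slices("axial"),
            count_rule=count_rule,
        )

    def distribution(self, projection: str, coordinate: int, model_kind: str = "real"):
        """Replica AUC distribution summary of one slice."""
        sub = self.auc_slices.query(
            "projection == @projection and coordinate == @coordinate "
            "and model_kind == @model_kind"
        )
        if sub.empty:
            raise ValueError(f"no AUCs for {projection} slice {coordinate}")
        return summarize_distribution(
            sub["auc"].to_numpy(),
            unit={"projection": projection, "coordinate": coordinate, "model_kind": model_kind},
        )

    def report(self) -> dict:
        """Machine-readable run report covering every pipeline stage."""
        m = self.model
        labels = m.patients["label"]
        real = self.selection_summary
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            n_vox_product = self.voxel_map("product_of_counts").n_voxels
            n_vox_unique = self.voxel_map("unique_voxels").n_voxels
        return {
            "version": __version__,
            "seed": m.seed,
            "cohort": {
                "n_patients": int(len(m.patients)),
                "n_volumes": len(m.volumes),
            },
            "labeling": {
                "n_positive": int(labels.sum()),
                "n_negative": int((1 - labels).sum()),
                "prevalence": float(labels.mean()),
            },
            "geometry": {
                p: {
                    "n_slices": int(d.coordinates.size),
                    "slabs": sorted(int(s) for s in set(d.slabs)),
                }
                for p, d in self.datasets.items()
            },
            "training": {
                "n_replicas": len(self.replicas),
                "train_fraction": m.train_fraction,
                "n_discriminators_real": int(
                    len(enumerate_design(len(self.replicas), m.projections))
                ),
                "location_accuracy": self.location_accuracy,
                "replica_seeds": [s.seed for s in self.replicas],
            },
            "roc": {
                "n_slice_aucs": int(len(self.auc_slices)),
                "n_slab_aucs": int(len(self.auc_slabs)),
            },
            "selection": real,
            "mapping": {
                "n_voxels_product_rule": n_vox_product,
                "n_voxels_unique_rule": n_vox_unique,
            },
        }

    def summary(self) -> str:
        """Human-readable results table."""
        m = self.model
        rep = self.report()
        lines = [
            "Slice-ensemble disability-progression analysis",
            "=" * 54,
            f"patients: {rep['cohort']['n_patients']}  "
            f"(progressed {rep['labeling']['n_positive']} / "
            f"stable {rep['labeling']['n_negative']})",
            f"replicas: {len(self.replicas)}  train fraction: {m.train_fraction:.2f}",
            f"projections: {', '.join(m.projections)}",
            f"selection: null AUC in 0.5 +/- delta, Z > {m.z_crit}, real AUC towards 1",
            "-" * 54,
        ]
        for p in m.projections:
            n_slices = rep["geometry"][p]["n_slices"]
            sel = self.significant_slices(p)
            acc = self.location_accuracy.get(p)
            acc_s = f"{acc:.2f}" if acc is not None else "n/a"
            rng = self.selection_summary["auc_real_ranges"].get(p)
            rng_s = f"[{rng[0]:.2f}-{rng[1]:.2f}]" if rng else "-"
            lines.append(
                f"{p:>9}: {n_slices:3d} slices | location acc {acc_s} | "
                f"{len(sel):3d} selected pairs | selected AUC {rng_s}"
            )
        lines += [
            "-" * 54,
            f"significant voxels: {rep['mapping']['n_voxels_product_rule']} "
            f"(product rule), {rep['mapping']['n_voxels_unique_rule']} (unique)",
            f"tests run without multiplicity correction: {self.selection_summary['n_tests']}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> dict:
        """Write all result tables, the JSON report and the voxel mask."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(directory / "predictions.csv", index=False)
        self.auc_slices.to_csv(directory / "auc_slices.csv", index=False)
        self.auc_slabs.to_csv(directory / "auc_slabs.csv", index=False)
        self.selection.to_csv(directory / "selection.csv", index=False)
        report = self.report()
        with open(directory / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            vmap = self.voxel_map("unique_voxels")
        if vmap.n_voxels and self.model.volumes:
            voxel_table(vmap).to_csv(directory / "voxels.csv", index=False)
            nib.save(export_mask(vmap, self.model.volumes[0]), str(directory / "mask.nii"))
        return report

    def plot_auc_distributions(self, projection: str, ax=None):
        """Boxplot of per-slice replica AUC distributions (real models)."""
        from .plotting import plot_auc_distributions

        return plot_auc_distributions(self, projection, ax=ax)
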