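import numpy as np
import pytest

from msprog import GeneratorConfig, SliceEnsembleModel, generate_cohort

#: Small voxel grid for generator tests that do not touch slab geometry.
TINY_GRID = (12, 14, 12)
TINY_REGION = (((3, 8), (4, 10), (3, 8)),)


def tiny_config(**overrides):
    kwargs = dict(
        n_patients=8,
        prevalence=0.5,
        grid_shape=TINY_GRID,
        signal_regions=TINY_REGION,
        effect_size=30.0,
        noise_sd=10.0,
        seed=5,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """24-patient full-grid cohort with a strong frontal signal box."""
    cfg = GeneratorConfig(
        n_patients=24, prevalence=0.34, seed=3, effect_size=40.0, noise_sd=15.0
    )
    return generate_cohort(cfg)


AXIAL_SIGNAL_BOX = ((30, 60), (78, 92), (40, 60))


@pytest.fixture(scope="session")
def axial_model():
    """Desk-scale model: 45 patients, axial projection, 6 replicas."""
    cfg = GeneratorConfig(
        n_patients=45,
        prevalence=1 / 3,
        seed=3,
        signal_regions=(AXIAL_SIGNAL_BOX,),
        effect_size=60.0,
        noise_sd=15.0,
    )
    cohort = generate_cohort(cfg)
    return SliceEnsembleModel(
        cohort.volumes,
        cohort.patients,
        n_replicas=6,
        train_fraction=0.8,
        projections=("axial",),
        seed=11,
    )


@pytest.fixture(scope="session")
def axial_results(axial_model):
    return axial_model.fit()


def brute_force_auc(scores, labels) -> float:
    """Independent pair-counting AUC oracle (ties credited 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
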