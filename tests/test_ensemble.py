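import numpy as np
import pandas as pd
import pytest

from msprog import (
    ClassifierSpec,
    auc_slice,
    build_slice_dataset,
    enumerate_design,
    make_replicas,
    pretrain_location,
    train_discriminator,
)
from msprog.ensemble import ReplicaSplit, SliceDataset, replica_seed

from conftest import brute_force_auc


def _cohort_table(n_neg, n_pos):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:03d}" for i in range(n_neg + n_pos)],
            "label": [0] * n_neg + [1] * n_pos,
        }
    )


# -- replica construction ----------------------------------------------


def test_study_cohort_stratification_is_exact():
    """119/62 cohort at 90%: every replica is 163 train (107/56), 18 val (12/6)."""
    splits = make_replicas(_cohort_table(119, 62), n_replicas=25, seed=4)
    table = _cohort_table(119, 62).set_index("patient_id")["label"]
    for s in splits:
        assert len(s.train_ids) == 163 and len(s.val_ids) == 18
        train_labels = table[s.train_ids]
        val_labels = table[s.val_ids]
        assert (train_labels == 0).sum() == 107 and (train_labels == 1).sum() == 56
        assert (val_labels == 0).sum() == 12 and (val_labels == 1).sum() == 6
        assert not set(s.train_ids) & set(s.val_ids)
        assert sorted(s.train_ids + s.val_ids) == sorted(table.index)


def test_small_cohort_stratification():
    splits = make_replicas(_cohort_table(5, 5), n_replicas=3, train_fraction=0.8, seed=0)
    table = _cohort_table(5, 5).set_index("patient_id")["label"]
    for s in splits:
        assert len(s.train_ids) == 8 and len(s.val_ids) == 2
        assert table[s.train_ids].sum() == 4
        assert table[s.val_ids].sum() == 1


def test_replicas_overlap_but_differ():
    splits = make_replicas(_cohort_table(20, 10), n_replicas=10, seed=1)
    val_sets = [frozenset(s.val_ids) for s in splits]
    assert len(set(val_sets)) > 1  # resamples differ
    # a patient can sit in several training sets
    counts = pd.Series(
        [p for s in splits for p in s.train_ids]
    ).value_counts()
    assert counts.max() > 1


def test_replicas_deterministic_given_seed():
    a = make_replicas(_cohort_table(20, 10), n_replicas=5, seed=7)
    b = make_replicas(_cohort_table(20, 10), n_replicas=5, seed=7)
    assert [(s.train_ids, s.val_ids, s.seed) for s in a] == [
        (s.train_ids, s.val_ids, s.seed) for s in b
    ]
    assert [s.seed for s in a] == [replica_seed(7, r) for r in range(1, 6)]


def test_tiny_class_cannot_stratify():
    with pytest.raises(ValueError, match="stratify"):
        make_replicas(_cohort_table(10, 1), n_replicas=2, seed=0)


@pytest.mark.parametrize("n_neg, n_pos", [(13, 7), (23, 11), (40, 17)])
def test_stratification_within_one_of_proportional(n_neg, n_pos):
    splits = make_replicas(_cohort_table(n_neg, n_pos), n_replicas=3, seed=2)
    table = _cohort_table(n_neg, n_pos).set_index("patient_id")["label"]
    for s in splits:
        for y, n_class in ((0, n_neg), (1, n_pos)):
            got = (table[s.train_ids] == y).sum()
            assert abs(got - 0.9 * n_class) <= 1


# -- design enumeration -------------------------------------------------


def test_full_design_enumerates_1200_discriminators():
    design = enumerate_design()
    assert len(design) == 1200
    assert design.drop_duplicates().shape[0] == 1200


def test_scaled_design_enumeration():
    assert len(enumerate_design(12, ("axial",), 4)) == 48


# -- slab-location pre-training -----------------------------------------


@pytest.fixture(scope="module")
def coronal_dataset(small_cohort):
    return build_slice_dataset(small_cohort.volumes, small_cohort.labels, "coronal")


def test_location_pretraining_separates_slabs(coronal_dataset):
    """Slabs are spatially disjoint, so location is decodable near-perfectly."""
    backbone = ClassifierSpec().build()
    acc = pretrain_location(backbone, coronal_dataset, seed=1)
    assert acc > 0.9
    assert backbone.pretrained


def test_location_chance_level_with_permuted_slabs(coronal_dataset):
    backbone = ClassifierSpec().build()
    feats = coronal_dataset.features(backbone)
    n_c, n_p, d = feats.shape
    x = feats.reshape(n_c * n_p, d)
    y = np.repeat(coronal_dataset.slabs, n_p)
    rng = np.random.default_rng(0)
    acc = backbone.fit_location(x, rng.permutation(y), seed=1)
    assert 0.10 < acc < 0.45  # 4-class chance, slab sizes slightly unequal


def test_location_requires_all_four_slabs(coronal_dataset):
    keep = coronal_dataset.slabs == 1
    single = SliceDataset(
        projection="coronal",
        patient_ids=coronal_dataset.patient_ids,
        labels=coronal_dataset.labels,
        coordinates=coronal_dataset.coordinates[keep],
        slabs=coronal_dataset.slabs[keep],
        pixels=coronal_dataset.pixels[keep],
    )
    with pytest.raises(ValueError, match="slabs"):
        pretrain_location(ClassifierSpec().build(), single, seed=0)


# -- discriminator training ---------------------------------------------


def _separable_dataset(n_patients=12, n_coords=3):
    """Toy dataset whose positive-class slices are uniformly brighter."""
    rng = np.random.default_rng(0)
    labels = np.array([0, 1] * (n_patients // 2))
    pixels = rng.normal(100.0, 1.0, size=(n_coords, n_patients, 10, 10))
    pixels[:, labels == 1] += 50.0
    return SliceDataset(
        projection="axial",
        patient_ids=[f"p{i}" for i in range(n_patients)],
        labels=labels,
        coordinates=np.array([30, 31, 32]),
        slabs=np.array([2, 2, 2]),
        pixels=pixels.astype(np.float32),
    )


def _split_for(ds, n_val=4):
    ids = np.array(ds.patient_ids)
    val = list(ids[:n_val])
    train = list(ids[n_val:])
    return ReplicaSplit(1, train, val, seed=123)


def test_separable_slab_gives_validation_auc_one():
    ds = _separable_dataset()
    preds = train_discriminator(ClassifierSpec().build(), ds, _split_for(ds), slab_id=2)
    assert set(preds["model_kind"]) == {"real"}
    assert len(preds) == 3 * 4  # slices x validation patients
    for _, grp in preds.groupby("coordinate"):
        r = auc_slice(grp["score"].to_numpy(), grp["true_label"].to_numpy())
        assert r.auc == 1.0
        assert r.auc == brute_force_auc(grp["score"], grp["true_label"])


def test_null_training_permutes_labels_but_not_validation():
    ds = _separable_dataset()
    split = _split_for(ds)
    real = train_discriminator(ClassifierSpec().build(), ds, split, 2, shuffle_labels=False)
    null = train_discriminator(ClassifierSpec().build(), ds, split, 2, shuffle_labels=True)
    # identical validation rows (patients, truth), different model kind
    pd.testing.assert_frame_equal(
        real[["coordinate", "patient_id", "true_label"]],
        null[["coordinate", "patient_id", "true_label"]],
    )
    assert set(null["model_kind"]) == {"null"}


def test_label_permutation_preserves_class_counts():
    from msprog.ensemble import _permute_labels

    labels = np.array([0] * 9 + [1] * 4)
    rng = np.random.default_rng(3)
    permuted = _permute_labels(labels, rng)
    assert sorted(permuted) == sorted(labels)
    assert not np.array_equal(permuted, labels)


def test_empty_slab_is_an_error():
    ds = _separable_dataset()
    with pytest.raises(ValueError, match="slab 4"):
        train_discriminator(ClassifierSpec().build(), ds, _split_for(ds), slab_id=4)


def test_classifier_spec_rejects_unknown_backbone():
    with pytest.raises(ValueError, match="backbone"):
        ClassifierSpec(backbone="resnet50").build()
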