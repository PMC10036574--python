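import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from qsarscreen import (
    DescriptorMatrix,
    ModelConfig,
    SyntheticSpec,
    ValidationError,
    fit_ad,
    generate_dataset,
    generate_screening_library,
    in_ad,
    y_randomization,
)

FAST_RF = {"n_estimators": 50}


def split(ds, seed=0):
    ids = np.array(ds.descriptors.compound_ids)
    tr, te = train_test_split(np.arange(len(ids)), test_size=0.2,
                              stratify=ds.labels, random_state=seed)
    return (
        ds.descriptors.subset_rows(ids[tr].tolist()),
        ds.labels[tr],
        ds.descriptors.subset_rows(ids[te].tolist()),
        ds.labels[te],
    )


class TestApplicabilityDomain:
    def test_training_compounds_inside_their_own_ad(self, dataset, ad_model):
        inside, _ = in_ad(ad_model, dataset.descriptors)
        assert inside.all()

    def test_two_components_give_two_bound_pairs(self, ad_model):
        assert ad_model.bounds.shape == (2, 2)
        assert ad_model.n_components == 2

    def test_component_variances_non_increasing(self, dataset):
        ad = fit_ad(dataset.descriptors, n_components=5)
        assert (np.diff(ad.explained_variance) <= 1e-12).all()

    def test_loadings_orthonormal(self, ad_model):
        G = ad_model.loadings @ ad_model.loadings.T
        assert np.allclose(G, np.eye(ad_model.n_components), atol=1e-10)

    def test_far_shifted_decoys_flagged_outside(self, dataset, ad_model):
        X, _ = generate_screening_library(
            300, frac_shifted=1.0, shift=10.0, seed=8,
            descriptor_names=dataset.descriptors.descriptor_names,
        )
        inside, _ = in_ad(ad_model, X)
        assert (~inside).mean() >= 0.95

    def test_margin_never_flips_inside_to_outside(self, dataset, ad_model):
        X, _ = generate_screening_library(
            300, frac_shifted=0.5, shift=3.0, seed=9,
            descriptor_names=dataset.descriptors.descriptor_names,
        )
        tight, _ = in_ad(ad_model, X, margin=0.0)
        wide, _ = in_ad(ad_model, X, margin=0.5)
        assert (wide | ~tight).all()

    def test_flags_invariant_to_descriptor_column_order(self, dataset, ad_model, rng):
        X, _ = generate_screening_library(
            100, frac_shifted=0.5, shift=3.0, seed=10,
            descriptor_names=dataset.descriptors.descriptor_names,
        )
        base, _ = in_ad(ad_model, X)
        shuffled = DescriptorMatrix(
            X.frame[list(rng.permutation(X.descriptor_names))]
        )
        permuted, _ = in_ad(ad_model, shuffled)
        assert (base == permuted).all()

    def test_excess_components_rejected(self):
        ds = generate_dataset(SyntheticSpec(n_active=3, n_inactive=3, seed=1))
        with pytest.raises(ValidationError):
            fit_ad(ds.descriptors, n_components=10)

    def test_missing_descriptor_named_in_error(self, dataset, ad_model):
        probe = dataset.descriptors.select(dataset.descriptors.descriptor_names[:5])
        with pytest.raises(ValidationError, match="missing"):
            in_ad(ad_model, probe)

    def test_convex_hull_criterion_contains_training_points(self, dataset, ad_model):
        inside, _ = in_ad(ad_model, dataset.descriptors, criterion="hull")
        assert inside.mean() >= 0.99

    def test_json_roundtrip(self, dataset, ad_model, tmp_path):
        path = tmp_path / "ad.json"
        ad_model.to_json(path)
        from qsarscreen import ADModel

        loaded = ADModel.from_json(path)
        i1, s1 = in_ad(ad_model, dataset.descriptors)
        i2, s2 = in_ad(loaded, dataset.descriptors)
        assert (i1 == i2).all() and np.allclose(s1, s2)


@pytest.fixture(scope="module")
def yrand_small(dataset):
    X_tr, y_tr, X_te, y_te = split(dataset)
    result = y_randomization(
        X_tr, y_tr, ModelConfig("random_forest", FAST_RF, seed=0),
        X_te, y_te, n_runs=30, resample_fraction=0.5, seed=7,
    )
    return result


class TestYRandomization:
    def test_scrambled_models_hover_at_chance(self, yrand_small):
        # balanced classes: chance accuracy 0.5; 30 runs, generous 3 SE band
        assert abs(yrand_small.mean_accuracy - 0.5) < 0.1
        assert abs(yrand_small.mean_auc - 0.5) < 0.1

    def test_reference_model_beats_every_scrambled_run(self, yrand_small):
        assert yrand_small.reference_accuracy > yrand_small.max_accuracy

    def test_values_bounded_and_counted(self, yrand_small):
        assert len(yrand_small.accuracies) == 30
        assert ((yrand_small.accuracies >= 0) & (yrand_small.accuracies <= 1)).all()
        assert ((yrand_small.aucs >= 0) & (yrand_small.aucs <= 1)).all()

    def test_identity_permutation_at_full_fraction_recovers_reference(self, dataset):
        X_tr, y_tr, X_te, y_te = split(dataset)
        res = y_randomization(
            X_tr, y_tr, ModelConfig("random_forest", FAST_RF, seed=4),
            X_te, y_te, n_runs=2, resample_fraction=1.0, seed=11,
            identity_permutation=True,
        )
        assert res.accuracies[0] == res.reference_accuracy
        assert res.aucs[0] == res.reference_auc

    def test_per_run_seeding_reproducible(self, dataset):
        X_tr, y_tr, X_te, y_te = split(dataset)
        kwargs = dict(n_runs=3, resample_fraction=0.5, seed=13)
        r1 = y_randomization(X_tr, y_tr, ModelConfig("random_forest", FAST_RF, seed=0),
                             X_te, y_te, **kwargs)
        r2 = y_randomization(X_tr, y_tr, ModelConfig("random_forest", FAST_RF, seed=0),
                             X_te, y_te, **kwargs)
        assert (r1.accuracies == r2.accuracies).all()

    def test_invalid_fraction_rejected(self, dataset):
        X_tr, y_tr, X_te, y_te = split(dataset)
        with pytest.raises(ValidationError):
            y_randomization(X_tr, y_tr, ModelConfig("random_forest"),
                            X_te, y_te, n_runs=2, resample_fraction=0.0)

    def test_single_class_labels_rejected(self, dataset):
        X_tr, y_tr, X_te, y_te = split(dataset)
        with pytest.raises(ValidationError):
            y_randomization(X_tr, np.ones_like(y_tr), ModelConfig("random_forest"),
                            X_te, y_te, n_runs=2)
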