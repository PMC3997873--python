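import numpy as np
import pytest

from dermamiml.imaging_io import Bag
from dermamiml.miml_gp import random_base_learners
from dermamiml.sparse_ensemble import (
    EnsembleModel,
    diagnose,
    ensemble_predict,
    fit_rvm,
    load_ensemble,
    normalize_weights,
    save_ensemble,
    train_ensemble,
)
from dermamiml.synthetic_data import generate_bags


class TestFitRvm:
    def test_exactly_predictive_column_dominates(self):
        """A column equal to the targets carries all the evidence; every
        noise column must be pruned."""
        rng = np.random.default_rng(0)
        phi = rng.random((120, 12))
        y = (rng.random(120) < 0.5).astype(float)
        phi[:, 3] = y
        w, alpha, pruned = fit_rvm(phi, y)
        assert not pruned[3]
        assert pruned.sum() == 11
        assert w[3] > 0

    def test_single_learner_survives(self):
        rng = np.random.default_rng(1)
        phi = rng.random((60, 1))
        y = (phi[:, 0] > 0.5).astype(float)
        w, alpha, pruned = fit_rvm(phi, y)
        assert not pruned[0]
        np.testing.assert_allclose(normalize_weights(np.clip(w, 0, None)), [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_two_sparse_combination(self, seed):
        rng = np.random.default_rng(100 + seed)
        phi = rng.random((200, 50))
        y = (0.6 * phi[:, 7] + 0.4 * phi[:, 23] > 0.5).astype(float)
        w, alpha, pruned = fit_rvm(phi, y)
        surviving = set(np.flatnonzero(~pruned).tolist())
        assert {7, 23} <= surviving
        assert len(surviving) <= 6

    def test_over_aggressive_pruning_raises(self):
        rng = np.random.default_rng(2)
        phi = rng.random((40, 3)) * 1e-4  # uninformative design
        y = (rng.random(40) < 0.5).astype(float)
        with pytest.raises(ValueError, match="pruned"):
            fit_rvm(phi, y, alpha_prune=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="binary"):
            fit_rvm(np.ones((4, 2)), np.array([0.0, 0.5, 1.0, 0.0]))
        with pytest.raises(ValueError, match="finite"):
            fit_rvm(np.full((2, 2), np.nan), np.array([0.0, 1.0]))


class TestNormalizeWeights:
    def test_direct_evaluation(self):
        np.testing.assert_allclose(normalize_weights([1.0, 3.0]), [0.25, 0.75])

    def test_zero_entry_preserved(self):
        np.testing.assert_allclose(normalize_weights([0.0, 5.0]), [0.0, 1.0])

    def test_sum_is_exactly_one(self):
        rng = np.random.default_rng(0)
        w = normalize_weights(rng.random(50))
        assert abs(w.sum() - 1.0) < 1e-12

    def test_zero_and_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights([0.0, 0.0])
        with pytest.raises(ValueError):
            normalize_weights([-1.0, 2.0])


@pytest.fixture(scope="module")
def trained_model():
    from dermamiml.synthetic_data import SynthConfig

    cfg = SynthConfig(
        n_terms=3, term_frequencies=(0.5, 0.4, 0.4), instance_dim=2,
        instance_range=(2, 4), effect_separation=4.0, regions_per_image=3,
    )
    bags, labels = generate_bags(cfg, 30, rng_seed=4)
    model = train_ensemble(
        bags, labels, q=8, seed=1, subsample=0.7, learner_max_iter=15,
    )
    return model, bags, labels


class TestEnsemblePredict:
    def test_single_survivor_equals_that_learner(self, trained_model):
        model, bags, _ = trained_model
        keep = int(np.argmax(model.weights))
        solo = EnsembleModel(
            learners=model.learners,
            weights=np.eye(len(model.learners))[keep],
            alphas=model.alphas,
            pruned=~np.eye(len(model.learners), dtype=bool)[keep],
            feature_mean=model.feature_mean,
            feature_std=model.feature_std,
            vocabulary=model.vocabulary,
        )
        scaled = Bag(model._scale(bags[0].instances))
        np.testing.assert_allclose(
            ensemble_predict(solo, bags[0]),
            model.learners[keep].predict(scaled),
            atol=1e-12,
        )

    def test_two_learner_average(self, trained_model):
        model, bags, _ = trained_model
        w = np.zeros(len(model.learners))
        w[0] = w[1] = 0.5
        half = EnsembleModel(
            learners=model.learners, weights=w, alphas=model.alphas,
            pruned=w == 0, feature_mean=model.feature_mean,
            feature_std=model.feature_std, vocabulary=model.vocabulary,
        )
        scaled = Bag(model._scale(bags[0].instances))
        expected = 0.5 * (
            model.learners[0].predict(scaled) + model.learners[1].predict(scaled)
        )
        np.testing.assert_allclose(ensemble_predict(half, bags[0]), expected, atol=1e-12)

    def test_convexity_bounds(self, trained_model):
        model, bags, _ = trained_model
        for bag in bags[:5]:
            scaled = Bag(model._scale(bag.instances))
            members = np.array([
                ln.predict(scaled)
                for ln, w in zip(model.learners, model.weights) if w > 0
            ])
            p = ensemble_predict(model, bag)
            assert (p >= members.min(axis=0) - 1e-12).all()
            assert (p <= members.max(axis=0) + 1e-12).all()

    def test_removing_zero_weight_learner_changes_nothing(self, trained_model):
        model, bags, _ = trained_model
        if model.pruned.any():
            keep = ~model.pruned
            reduced = EnsembleModel(
                learners=[ln for ln, k in zip(model.learners, keep) if k],
                weights=model.weights[keep],
                alphas=model.alphas[keep],
                pruned=np.zeros(int(keep.sum()), dtype=bool),
                feature_mean=model.feature_mean,
                feature_std=model.feature_std,
                vocabulary=model.vocabulary,
            )
            for bag in bags[:5]:
                np.testing.assert_allclose(
                    ensemble_predict(reduced, bag), ensemble_predict(model, bag),
                    atol=1e-12,
                )

    def test_weights_sum_to_one(self, trained_model):
        model, _, _ = trained_model
        assert abs(model.weights.sum() - 1.0) < 1e-12
        assert (model.weights[model.pruned] == 0).all()

    def test_serialization_round_trip(self, trained_model, tmp_path):
        model, bags, _ = trained_model
        path = tmp_path / "model.npz"
        save_ensemble(model, path)
        back = load_ensemble(path)
        assert back.vocabulary == model.vocabulary
        np.testing.assert_allclose(back.weights, model.weights)
        for bag in bags[:3]:
            np.testing.assert_allclose(
                ensemble_predict(back, bag), ensemble_predict(model, bag), atol=1e-10,
            )


class TestDiagnose:
    def test_point_mass_term_maps_to_its_disease(self):
        table = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = diagnose([1.0, 0.0], table)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_uniform_conditionals_give_uniform_diseases(self):
        table = np.full((3, 4), 0.25)
        out = diagnose([0.2, 0.9, 0.4], table)
        np.testing.assert_allclose(out, 0.25)

    def test_two_term_two_disease_hand_computation(self):
        table = np.array([[0.8, 0.2], [0.3, 0.7]])
        p_t = np.array([0.6, 0.5])
        raw = p_t @ table  # [0.63, 0.47]
        out = diagnose(p_t, table)
        np.testing.assert_allclose(out, raw / raw.sum())

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            diagnose([0.5], np.array([[0.5, 0.4]]))  # row does not sum to 1
        with pytest.raises(ValueError):
            diagnose([1.5], np.array([[1.0]]))       # probability out of range
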