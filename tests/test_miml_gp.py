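import numpy as np
import pytest

from dermamiml.imaging_io import Bag, TermVector
from dermamiml.miml_gp import (
    InstanceKernel,
    TermCovariance,
    bag_softmax,
    laplace_fit,
    predict,
    sample_term_covariance,
)
from dermamiml.synthetic_data import SynthConfig, generate_bags

VOCAB1 = ("term1",)
VOCAB2 = ("term1", "term2")


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


class TestSampleTermCovariance:
    def test_single_term_is_unit(self):
        np.testing.assert_allclose(sample_term_covariance(1, 0).matrix, [[1.0]])

    @pytest.mark.parametrize("s,seed", [(2, 0), (5, 1), (8, 42), (15, 7)])
    def test_psd_with_unit_diagonal(self, s, seed):
        m = sample_term_covariance(s, seed).matrix
        assert np.linalg.eigvalsh(m).min() >= -1e-10
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)

    def test_deterministic_in_seed(self):
        a = sample_term_covariance(6, 3).matrix
        b = sample_term_covariance(6, 3).matrix
        np.testing.assert_array_equal(a, b)

    def test_validation_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            TermCovariance(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PSD
        with pytest.raises(ValueError):
            TermCovariance(np.array([[2.0, 0.0], [0.0, 2.0]]))  # diag != 1


class TestBagSoftmax:
    def test_constant_activations_pass_through(self):
        for c in (-3.0, 0.0, 7.5):
            assert bag_softmax([c, c, c]) == pytest.approx(c)

    def test_mean_and_sum_modes_on_zeros(self):
        assert bag_softmax([0.0, 0.0], mode="mean") == pytest.approx(0.0)
        assert bag_softmax([0.0, 0.0], mode="sum") == pytest.approx(np.log(2))

    def test_bounds_and_direct_evaluation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5) * 3
        lme = bag_softmax(a)
        assert a.max() - np.log(5) <= lme <= a.max()
        assert lme == pytest.approx(np.log(np.mean(np.exp(a))))

    def test_overflow_safe(self):
        assert bag_softmax([1000.0, 999.0]) == pytest.approx(
            1000.0 + np.log((1 + np.exp(-1)) / 2)
        )

    def test_monotone_in_every_argument(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=6)
        base = bag_softmax(a)
        for i in range(6):
            bumped = a.copy()
            bumped[i] += 0.5
            assert bag_softmax(bumped) > base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bag_softmax([])


def _toy_single_instance_problem():
    bags = [Bag([[0.0]]), Bag([[1.0]])]
    labels = [TermVector(np.array([1], dtype=np.int8), VOCAB1),
              TermVector(np.array([0], dtype=np.int8), VOCAB1)]
    kernel = InstanceKernel(lengthscale=1.0, variance=1.0)
    return bags, labels, kernel


class TestLaplaceFit:
    def test_mode_matches_grid_search_oracle(self):
        """Two single-instance bags, one term: the posterior mode must agree
        with an exhaustive 2-D grid optimization of the log posterior."""
        bags, labels, kernel = _toy_single_instance_problem()
        tc = TermCovariance(np.eye(1))
        learner = laplace_fit(bags, labels, tc, kernel, max_iter=100, tol=1e-10)

        X = np.array([[0.0], [1.0]])
        K = kernel.gram(X) + 1e-6 * np.eye(2)
        Kinv = np.linalg.inv(K)
        y = np.array([1.0, 0.0])

        def psi(f1, f2):
            f = np.stack([f1, f2], axis=-1)
            # bernoulli log-lik written explicitly for y = [1, 0]
            ll = -np.logaddexp(0, -f1) - np.logaddexp(0, f2)
            quad = -0.5 * np.einsum("...i,ij,...j->...", f, Kinv, f)
            return ll + quad

        # coarse grid then a fine grid around the best cell
        g = np.linspace(-4, 4, 161)
        F1, F2 = np.meshgrid(g, g, indexing="ij")
        vals = psi(F1, F2)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        g1 = np.linspace(g[i] - 0.06, g[i] + 0.06, 1201)
        g2 = np.linspace(g[j] - 0.06, g[j] + 0.06, 1201)
        F1, F2 = np.meshgrid(g1, g2, indexing="ij")
        vals = psi(F1, F2)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert learner.F_hat[0, 0] == pytest.approx(g1[i], abs=1e-4)
        assert learner.F_hat[0, 1] == pytest.approx(g2[j], abs=1e-4)

    def test_gradient_norm_below_tolerance_at_mode(self):
        bags, labels, kernel = _toy_single_instance_problem()
        tol = 1e-9
        learner = laplace_fit(
            bags, labels, TermCovariance(np.eye(1)), kernel,
            max_iter=200, tol=tol,
        )
        assert learner.converged

    def test_all_positive_term_has_nonnegative_mode(self):
        rng = np.random.default_rng(0)
        bags = [Bag(rng.normal(size=(3, 2))) for _ in range(6)]
        bits = [(1, 1), (1, 0), (1, 1), (1, 0), (1, 1), (1, 0)]
        labels = [TermVector(np.array(b, dtype=np.int8), VOCAB2) for b in bits]
        learner = laplace_fit(
            bags, labels, TermCovariance(np.eye(2)),
            InstanceKernel(lengthscale=1.5), max_iter=100, tol=1e-8,
        )
        assert (learner.F_hat[0] >= -1e-8).all()

    def test_rejects_degenerate_inputs(self):
        bags, labels, kernel = _toy_single_instance_problem()
        with pytest.raises(ValueError):
            laplace_fit(bags[:1], labels[:1], TermCovariance(np.eye(1)), kernel)
        all_pos = [TermVector(np.array([1], dtype=np.int8), VOCAB1)] * 2
        with pytest.raises(ValueError, match="both label values"):
            laplace_fit(bags, all_pos, TermCovariance(np.eye(1)), kernel)


class TestPredict:
    def _fit(self, term_cov, bags, labels, **kw):
        kernel = InstanceKernel(lengthscale=2.0, variance=4.0)
        return laplace_fit(bags, labels, term_cov, kernel, **kw)

    def test_identity_term_covariance_decouples_terms(self):
        """K_term = I must reproduce two independently fitted per-term
        learners to numerical precision (Kronecker prior factorizes)."""
        cfg = SynthConfig(
            n_terms=2, term_frequencies=(0.5, 0.4), instance_dim=2,
            instance_range=(2, 4), effect_separation=4.0, regions_per_image=3,
        )
        bags, labels = generate_bags(cfg, 10, rng_seed=2)
        joint = self._fit(TermCovariance(np.eye(2)), bags, labels,
                          max_iter=300, tol=1e-11)
        per_term = []
        for t in range(2):
            labs = [TermVector(np.array([l.bits[t]]), VOCAB1) for l in labels]
            ln = self._fit(TermCovariance(np.eye(1)), bags, labs,
                           max_iter=300, tol=1e-11)
            per_term.append(np.array([predict(ln, b)[0] for b in bags]))
        pj = np.array([predict(joint, b) for b in bags])
        np.testing.assert_allclose(pj, np.array(per_term).T, atol=1e-6)

    def test_vanishing_kernel_variance_gives_indifferent_predictions(self):
        bags, labels, _ = _toy_single_instance_problem()
        kernel = InstanceKernel(lengthscale=1.0, variance=1e-10)
        learner = laplace_fit(bags, labels, TermCovariance(np.eye(1)), kernel,
                              max_iter=50, tol=1e-8)
        for b in bags:
            assert predict(learner, b)[0] == pytest.approx(0.5, abs=1e-3)

    def test_outputs_are_probabilities(self, small_bags):
        bags, labels = small_bags
        tc = sample_term_covariance(5, 3)
        learner = laplace_fit(bags, labels, tc, InstanceKernel(lengthscale=3.0),
                              max_iter=30, tol=1e-4)
        for b in bags[:5]:
            p = predict(learner, b)
            assert p.shape == (5,)
            assert np.isfinite(p).all()
            assert ((p >= 0) & (p <= 1)).all()

    def test_separable_training_bags_predicted_on_correct_side(self, small_bags):
        bags, labels = small_bags
        learner = laplace_fit(
            bags, labels, TermCovariance(np.eye(5)),
            InstanceKernel(lengthscale=2.0, variance=16.0),
            max_iter=60, tol=1e-6,
        )
        probs = np.array([predict(learner, b) for b in bags])
        truth = np.array([l.bits for l in labels])
        assert ((probs >= 0.5).astype(int) == truth).mean() >= 0.85

    def test_dimension_mismatch_rejected(self):
        bags, labels, kernel = _toy_single_instance_problem()
        learner = laplace_fit(bags, labels, TermCovariance(np.eye(1)), kernel)
        with pytest.raises(ValueError, match="dimension"):
            predict(learner, Bag([[0.0, 1.0]]))
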