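"""Bayesian multi-instance multi-label base learner.

One learner models ``s`` latent functions (one per annotation term) over
instance space with a joint Gaussian prior ``vec(F) ~ N(0, K_term (x) K)``:
the Kronecker factor ``K_term`` (s x s, unit diagonal) encodes correlation
*between terms*, while ``K`` is an ordinary RBF gram matrix over instances.
A bag's activation for term ``i`` aggregates the instance latents with a
soft max (log-mean-exp by default), realizing the standard multi-instance
assumption: one strongly positive instance suffices to label the bag.  The
bag label is Bernoulli through a logistic link on that activation.

The non-Gaussian posterior over ``F`` is handled with a Laplace
approximation: a damped-Newton search for the posterior mode followed by a
Gaussian with the negative-Hessian curvature.  Prediction propagates the
Gaussian for a test bag's latents through the soft max by linearization and
integrates the logistic link with Gauss-Hermite quadrature.

Term covariances for ensemble members are *sampled at random* rather than
optimized; an ARD-weighted combination downstream picks out the useful ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, cdist
from scipy.special import logsumexp, softmax

from .imaging_io import Bag, TermVector

logger = logging.getLogger(__name__)

JITTER = 1e-6
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(20)


@dataclass(frozen=True)
class TermCovariance:
    """Symmetric PSD term-relationship matrix with unit diagonal."""

    matrix: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("term covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("term covariance must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("term covariance must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("term covariance must be positive semidefinite")
        object.__setattr__(self, "matrix", m)

    @property
    def s(self) -> int:
        return self.matrix.shape[0]


def sample_term_covariance(s: int, seed: int) -> TermCovariance:
    """Random PSD unit-diagonal term covariance: ``WW^T`` rescaled.

    ``W`` is s x s standard normal; a small ridge keeps the result strictly
    positive definite before rescaling to unit diagonal.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((s, s))
    m = w @ w.T + 1e-6 * np.eye(s)
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return TermCovariance((m + m.T) / 2.0, seed=seed)


@dataclass(frozen=True)
class InstanceKernel:
    """RBF kernel over instance feature space."""

    lengthscale: float = 1.0
    variance: float = 1.0
    kind: str = "rbf"

    def __post_init__(self) -> None:
        if self.kind != "rbf":
            raise ValueError("only the RBF kernel is implemented")
        if self.lengthscale <= 0 or self.variance <= 0:
            raise ValueError("lengthscale and variance must be > 0")

    def gram(self, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        X = np.atleast_2d(X)
        Y = X if Y is None else np.atleast_2d(Y)
        d2 = cdist(X, Y, metric="sqeuclidean")
        return self.variance * np.exp(-d2 / (2.0 * self.lengthscale**2))


def bag_softmax(activations, mode: str = "mean") -> float:
    """Soft max aggregation of instance activations.

    ``mode='mean'`` (default) returns the log-mean-exp
    ``ln((1/n) sum_i e^{a_i})``; ``mode='sum'`` the plain log-sum-exp.  Both
    are computed overflow-safely and are monotone in every argument.
    """
    a = np.asarray(activations, dtype=float)
    if a.size == 0:
        raise ValueError("activations must be nonempty")
    if not np.isfinite(a).all():
        raise ValueError("activations must be finite")
    if mode == "mean":
        return float(logsumexp(a) - np.log(a.size))
    if mode == "sum":
        return float(logsumexp(a))
    raise ValueError("mode must be 'mean' or 'sum'")


def _sigmoid(a):
    return 0.5 * (1.0 + np.tanh(0.5 * a))


def _bag_ll_grad_hess(f: np.ndarray, y: int, mode: str):
    """Log-likelihood, gradient and negative Hessian block for one (term, bag)."""
    a = bag_softmax(f, mode=mode)
    p = _sigmoid(a)
    ll = -np.logaddexp(0.0, -a) if y == 1 else -np.logaddexp(0.0, a)
    s_w = softmax(f)
    grad = (y - p) * s_w
    outer = np.outer(s_w, s_w)
    hess_ll = (y - p) * (np.diag(s_w) - outer) - p * (1.0 - p) * outer
    return ll, grad, -hess_ll  # return W block = negative Hessian


@dataclass
class BaseLearner:
    """Fitted Laplace state of one GP MIML learner."""

    term_cov: TermCovariance
    kernel: InstanceKernel
    X_train: np.ndarray                  # (N, d) training instances
    F_hat: np.ndarray                    # (s, N) posterior mode
    K_chol: tuple                        # cho_factor of the instance gram
    sigma_blocks: np.ndarray             # (s, N, N) per-term posterior covariance
    softmax_mode: str = "mean"
    converged: bool = True
    bag_subset: np.ndarray | None = None  # indices of the bags it was fit on
    meta: dict = field(default_factory=dict)

    @property
    def s(self) -> int:
        return self.F_hat.shape[0]

    def predict(self, bag: Bag) -> np.ndarray:
        return predict(self, bag)


def _stack(bags: list[Bag]):
    X = np.vstack([b.instances for b in bags])
    idx, start = [], 0
    for b in bags:
        idx.append(np.arange(start, start + b.n_instances))
        start += b.n_instances
    return X, idx


def laplace_fit(
    bags: list[Bag],
    labels: list[TermVector],
    term_cov: TermCovariance,
    kernel: InstanceKernel,
    max_iter: int = 60,
    tol: float = 1e-6,
    softmax_mode: str = "mean",
) -> BaseLearner:
    """Find the Laplace posterior of the latent matrix ``F``.

    Damped (Levenberg-style) Newton iterations maximize
    ``log p(labels | F) + log p(F)``; the accepted objective never
    decreases.  Returns the learner with the mode, the instance-gram
    factorization and the per-term blocks of the posterior covariance.
    """
    if len(bags) < 2:
        raise ValueError("need at least 2 bags")
    if len(bags) != len(labels):
        raise ValueError("bags and labels must align")
    s = term_cov.s
    Y = np.array([lv.bits for lv in labels], dtype=int).T  # (s, B)
    if Y.shape[0] != s:
        raise ValueError("label length does not match term covariance size")
    if not ((Y.min(axis=1) == 0) & (Y.max(axis=1) == 1)).any():
        raise ValueError("at least one term needs both label values present")

    X, bag_idx = _stack(bags)
    N = X.shape[0]
    K = kernel.gram(X) + JITTER * np.eye(N)
    K_chol = cho_factor(K, lower=True)
    Kinv = cho_solve(K_chol, np.eye(N))
    Kgp = term_cov.matrix + JITTER * np.eye(s)
    Kgp_inv = np.linalg.inv(Kgp)
    Cinv = np.kron(Kgp_inv, Kinv)

    dim = s * N
    u = np.zeros(dim)

    def evaluate(u_vec):
        F = u_vec.reshape(s, N)
        ll = 0.0
        grad = np.zeros((s, N))
        W = np.zeros((dim, dim))
        for i in range(s):
            for j, idx in enumerate(bag_idx):
                l, g, wblk = _bag_ll_grad_hess(F[i, idx], Y[i, j], softmax_mode)
                ll += l
                grad[i, idx] += g
                rows = i * N + idx
                W[np.ix_(rows, rows)] += wblk
        psi = ll - 0.5 * u_vec @ (Cinv @ u_vec)
        g_full = grad.ravel() - Cinv @ u_vec
        return psi, g_full, W

    psi, g, W = evaluate(u)
    lam = 1e-4
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        H = W + Cinv
        accepted = False
        for _try in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(dim), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            u_new = u + step
            psi_new, g_new, W_new = evaluate(u_new)
            if psi_new >= psi - 1e-12:
                u, psi, g, W = u_new, psi_new, g_new, W_new
                lam = max(lam * 0.3, 1e-10)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
    else:
        converged = np.max(np.abs(g)) < tol
    if not converged and np.max(np.abs(g)) >= tol:
        logger.warning(
            "Laplace mode search stopped with gradient norm %.3g >= tol %.3g",
            np.max(np.abs(g)), tol,
        )

    # posterior covariance at the mode; ridge if the curvature is indefinite
    A = Cinv + W
    ridge = 0.0
    for _ in range(8):
        try:
            Sigma = cho_solve(cho_factor((A + A.T) / 2 + ridge * np.eye(dim), lower=True),
                              np.eye(dim))
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-8)
    else:
        Sigma = np.linalg.pinv((A + A.T) / 2)
    sigma_blocks = np.stack(
        [Sigma[i * N:(i + 1) * N, i * N:(i + 1) * N] for i in range(s)]
    )
    return BaseLearner(
        term_cov=term_cov,
        kernel=kernel,
        X_train=X,
        F_hat=u.reshape(s, N),
        K_chol=K_chol,
        sigma_blocks=sigma_blocks,
        softmax_mode=softmax_mode,
        converged=converged,
    )


def predict(learner: BaseLearner, bag: Bag) -> np.ndarray:
    """Per-term annotation probabilities for one bag, each in [0, 1].

    The Gaussian conditional of the bag's latents is pushed through the soft
    max by linearization at the predictive mean (delta method), and the
    logistic link is integrated with 20-point Gauss-Hermite quadrature.
    """
    X_star = np.atleast_2d(bag.instances)
    if X_star.shape[1] != learner.X_train.shape[1]:
        raise ValueError(
            f"bag dimension {X_star.shape[1]} does not match training "
            f"dimension {learner.X_train.shape[1]}"
        )
    Kx = learner.kernel.gram(learner.X_train, X_star)        # (N, n*)
    Kxx = learner.kernel.gram(X_star) + JITTER * np.eye(X_star.shape[0])
    V = cho_solve(learner.K_chol, Kx)                        # K^{-1} Kx
    M = learner.F_hat @ V                                    # (s, n*)
    Qx = Kxx - Kx.T @ V
    probs = np.empty(learner.s)
    for i in range(learner.s):
        f = M[i]
        cov_i = learner.term_cov.matrix[i, i] * Qx + V.T @ learner.sigma_blocks[i] @ V
        w = softmax(f)
        m_a = bag_softmax(f, mode=learner.softmax_mode)
        v_a = max(float(w @ cov_i @ w), 0.0)
        z = m_a + np.sqrt(2.0 * v_a) * _GH_X
        probs[i] = float(np.sum(_GH_W * _sigmoid(z)) / np.sqrt(np.pi))
    return np.clip(probs, 0.0, 1.0)


def median_lengthscale(bags: list[Bag], max_points: int = 500, seed: int = 0) -> float:
    """Median pairwise instance distance — the RBF lengthscale heuristic."""
    X, _ = _stack(bags)
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=max_points, replace=False)]
    d = pdist(X)
    med = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    return max(med, 1e-6)


def random_base_learners(
    bags: list[Bag],
    labels: list[TermVector],
    q: int,
    seed: int,
    subsample: float = 0.8,
    kernel_variance: float = 16.0,
    max_iter: int = 25,
    tol: float = 1e-4,
    softmax_mode: str = "mean",
    max_bags: int | None = None,
) -> list[BaseLearner]:
    """Generate ``q`` randomly parameterized learners for the ensemble.

    Diversity comes from three sources per member: a freshly sampled term
    covariance, a bag subsample (fraction ``subsample``), and an RBF
    lengthscale drawn log-uniformly within a factor e of the median-distance
    heuristic.  The kernel variance defaults to 16 (latent amplitude 4) so
    the logistic link can saturate — a unit-variance prior caps bag
    probabilities well inside (0, 1) and underfits.

    ``max_bags`` caps each member's training-set size regardless of the
    subsample fraction; deliberately tiny members keep large ensembles cheap
    and lean on the downstream weighting to sort them out.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = np.random.default_rng(seed)
    s = len(labels[0].bits)
    base_ls = median_lengthscale(bags, seed=seed)
    n_sub = max(2, int(round(subsample * len(bags))))
    if max_bags is not None:
        n_sub = min(n_sub, max_bags)
    learners = []
    for m in range(q):
        sub = np.sort(rng.choice(len(bags), size=n_sub, replace=False))
        term_cov = sample_term_covariance(s, seed=int(rng.integers(0, 2**31 - 1)))
        ls = base_ls * np.exp(rng.uniform(-1.0, 1.0))
        kernel = InstanceKernel(lengthscale=float(ls), variance=kernel_variance)
        sub_bags = [bags[i] for i in sub]
        sub_labels = [labels[i] for i in sub]
        try:
            learner = laplace_fit(
                sub_bags, sub_labels, term_cov, kernel,
                max_iter=max_iter, tol=tol, softmax_mode=softmax_mode,
            )
        except ValueError:
            # degenerate subsample (e.g. all labels constant): redraw wider
            sub = np.arange(len(bags))
            learner = laplace_fit(
                bags, labels, term_cov, kernel,
                max_iter=max_iter, tol=tol, softmax_mode=softmax_mode,
            )
        learner.bag_subset = sub
        learner.meta = {"member": m, "lengthscale": float(ls)}
        learners.append(learner)
    return learners
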