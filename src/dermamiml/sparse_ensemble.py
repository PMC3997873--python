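"""Sparse Bayesian (RVM/ARD) weighting of random MIML base learners.

``Q`` Gaussian-process MIML learners with randomly sampled term covariances
are combined linearly.  A relevance-vector-machine step places an automatic
relevance determination (ARD) prior — zero-mean Gaussians with individual
precisions ``alpha_i`` — on the combination weights; evidence maximization
drives most precisions to infinity, pruning the corresponding learners, and
the surviving weights are normalized to sum to one.  The ensemble prediction
is therefore a convex combination of the surviving learners' probability
outputs and stays in [0, 1].

The design the RVM regresses on has one row per (training bag, term) pair
and one column per learner, holding that learner's predicted probability;
the binary target says whether the term is truly annotated.  A
classification RVM (Bernoulli likelihood, Laplace) matches these targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor

from .imaging_io import Bag, TermVector, DEFAULT_VOCABULARY
from .miml_gp import (
    BaseLearner,
    InstanceKernel,
    TermCovariance,
    random_base_learners,
    _sigmoid,
)

logger = logging.getLogger(__name__)


def normalize_weights(w) -> np.ndarray:
    """Divide each weight by the total so the result sums to one."""
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    return w / total


def _penalized_logistic_map(phi, y, alpha, w0, max_iter=50, tol=1e-8):
    """MAP weights of the logistic model with per-weight Gaussian priors."""
    w = w0.copy()
    A = np.diag(alpha)

    def objective(wv):
        a = phi @ wv
        ll = -(np.logaddexp(0.0, -a)[y == 1].sum() + np.logaddexp(0.0, a)[y == 0].sum())
        return ll - 0.5 * wv @ (alpha * wv)

    obj = objective(w)
    for _ in range(max_iter):
        a = phi @ w
        p = _sigmoid(a)
        grad = phi.T @ (y - p) - alpha * w
        if np.max(np.abs(grad)) < tol:
            break
        b = np.clip(p * (1.0 - p), 1e-10, None)
        H = (phi * b[:, None]).T @ phi + A
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _half in range(30):
            w_new = w + t * step
            obj_new = objective(w_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        if obj_new < obj - 1e-12:
            break
        w, obj = w_new, obj_new
    a = phi @ w
    b = np.clip(_sigmoid(a) * (1.0 - _sigmoid(a)), 1e-10, None)
    H = (phi * b[:, None]).T @ phi + A
    return w, H


def fit_rvm(
    design: np.ndarray,
    targets: np.ndarray,
    alpha_prune: float = 1e12,
    max_iter: int = 300,
    tol: float = 1e-6,
    alpha_init: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ARD evidence iterations over learner-combination weights.

    Alternates a penalized-logistic re-estimation of the weights with
    Tipping's updates ``alpha_i <- gamma_i / w_i^2`` where
    ``gamma_i = 1 - alpha_i * Sigma_ii``.  Learners whose precision exceeds
    ``alpha_prune`` are pruned (weight fixed at zero).  As in Tipping's
    formulation the model carries a bias basis function with its own ARD
    precision; the bias absorbs the baseline log-odds and is dropped from
    the returned combination.  Returns ``(w, alpha, pruned)`` over the Q
    learner columns.
    """
    phi_in = np.asarray(design, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if phi_in.ndim != 2 or phi_in.shape[0] != y.size:
        raise ValueError("design must be 2-D with one row per target")
    if not np.isfinite(phi_in).all():
        raise ValueError("design must be finite")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")
    Q = phi_in.shape[1]
    phi = np.column_stack([phi_in, np.ones(len(y))])  # last column = bias

    active = np.arange(Q + 1)
    alpha = np.full(Q + 1, alpha_init)
    w_full = np.zeros(Q + 1)
    for _ in range(max_iter):
        if not (active < Q).any():
            raise ValueError(
                "all learners were pruned; increase Q or lower alpha_prune"
            )
        phi_a = phi[:, active]
        w_a, H = _penalized_logistic_map(phi_a, y, alpha[active], w_full[active])
        try:
            sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            sigma = np.linalg.pinv(H)
        gamma = np.clip(1.0 - alpha[active] * np.diag(sigma), 1e-12, 1.0)
        alpha_new = gamma / np.clip(w_a**2, 1e-300, None)

        w_prev = w_full.copy()
        w_full[:] = 0.0
        w_full[active] = w_a
        d_log_alpha = np.max(np.abs(np.log(alpha_new) - np.log(alpha[active])))
        alpha[active] = alpha_new
        keep = alpha[active] <= alpha_prune
        active = active[keep]
        # stop only once the weights AND the ARD precisions have settled:
        # weights drift slowly while precisions still climb toward pruning
        if np.max(np.abs(w_full - w_prev)) < tol and d_log_alpha < 1e-2:
            break
    if not (active < Q).any():
        raise ValueError("all learners were pruned; increase Q or lower alpha_prune")
    pruned = np.ones(Q + 1, dtype=bool)
    pruned[active] = False
    w_full[pruned] = 0.0
    return w_full[:Q], alpha[:Q], pruned[:Q]


@dataclass
class EnsembleModel:
    """RVM-weighted ensemble of GP MIML base learners."""

    learners: list[BaseLearner]
    weights: np.ndarray              # normalized, sum 1, zeros where pruned
    alphas: np.ndarray
    pruned: np.ndarray
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    meta: dict = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return int((~self.pruned).sum())

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_std

    def predict(self, bag: Bag) -> np.ndarray:
        return ensemble_predict(self, bag)


def ensemble_predict(model: EnsembleModel, bag: Bag) -> np.ndarray:
    """Weighted average of surviving learners' term probabilities."""
    scaled = Bag(model._scale(bag.instances), source_id=bag.source_id,
                 region_ids=list(bag.region_ids))
    out = None
    for learner, w in zip(model.learners, model.weights):
        if w <= 0:
            continue
        p = learner.predict(scaled)
        out = w * p if out is None else out + w * p
    if out is None:
        raise ValueError("ensemble has no surviving learner")
    return np.clip(out, 0.0, 1.0)


def _design_matrix(learners, bags, Y):
    """Rows = (bag, term) pairs, bag-major; column i = learner i's probability."""
    B, s = Y.shape
    phi = np.empty((B * s, len(learners)))
    for col, learner in enumerate(learners):
        for j, bag in enumerate(bags):
            phi[j * s:(j + 1) * s, col] = learner.predict(bag)
    return phi


def train_ensemble(
    bags: list[Bag],
    labels: list[TermVector],
    q: int = 200,
    seed: int = 0,
    subsample: float = 0.8,
    kernel_variance: float = 16.0,
    alpha_prune: float = 1e12,
    learner_max_iter: int = 25,
    learner_tol: float = 1e-4,
    rvm_max_iter: int = 300,
    rvm_tol: float = 1e-6,
    standardize: bool = True,
    max_learner_bags: int | None = None,
) -> EnsembleModel:
    """Full ensemble training: random learners, RVM weighting, normalization.

    Features are z-scored over the training instances before entering the
    RBF kernel (the 26 region descriptors live on very different scales);
    the scaler is stored with the model.  Negative RVM weights are clipped
    to zero before normalization.
    """
    if len(bags) != len(labels):
        raise ValueError("bags and labels must align")
    X_all = np.vstack([b.instances for b in bags])
    if standardize:
        mean = X_all.mean(axis=0)
        std = np.where(X_all.std(axis=0) < 1e-12, 1.0, X_all.std(axis=0))
        scaled_bags = [
            Bag((b.instances - mean) / std, source_id=b.source_id,
                region_ids=list(b.region_ids))
            for b in bags
        ]
    else:
        mean = std = None
        scaled_bags = bags

    learners = random_base_learners(
        scaled_bags, labels, q=q, seed=seed, subsample=subsample,
        kernel_variance=kernel_variance,
        max_iter=learner_max_iter, tol=learner_tol, max_bags=max_learner_bags,
    )
    Y = np.array([lv.bits for lv in labels], dtype=float)
    phi = _design_matrix(learners, scaled_bags, Y)
    w, alpha, pruned = fit_rvm(
        phi, Y.ravel(), alpha_prune=alpha_prune,
        max_iter=rvm_max_iter, tol=rvm_tol,
    )
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        # every surviving weight was negative: keep the strongest learner
        best = int(np.argmax(np.abs(w)))
        logger.warning("all surviving weights non-positive; keeping learner %d", best)
        w[:] = 0.0
        w[best] = 1.0
        pruned[:] = True
        pruned[best] = False
    weights = normalize_weights(w)
    pruned = pruned | (weights <= 0)
    return EnsembleModel(
        learners=learners,
        weights=weights,
        alphas=alpha,
        pruned=pruned,
        feature_mean=mean,
        feature_std=std,
        vocabulary=labels[0].vocabulary,
        meta={"q": q, "seed": seed, "subsample": subsample},
    )


def diagnose(term_probs, term_to_disease) -> np.ndarray:
    """Disease mixture ``p(w | image) ∝ sum_t p(w | t) p(t | image)``.

    ``term_to_disease`` has one row per term, each a probability vector over
    diseases; the mixture is renormalized over diseases.
    """
    p_t = np.asarray(term_probs, dtype=float)
    table = np.asarray(term_to_disease, dtype=float)
    if p_t.ndim != 1 or table.ndim != 2 or table.shape[0] != p_t.size:
        raise ValueError("term_to_disease needs one row per term probability")
    if (p_t < 0).any() or (p_t > 1).any():
        raise ValueError("term probabilities must lie in [0, 1]")
    if (table < 0).any() or not np.allclose(table.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each row of term_to_disease must be a probability vector")
    mix = p_t @ table
    total = mix.sum()
    if total <= 0:
        raise ValueError("mixture has zero mass (all term probabilities are 0)")
    return mix / total


def save_ensemble(model: EnsembleModel, path) -> None:
    """Serialize an ensemble to one .npz archive plus JSON metadata inside."""
    path = Path(path)
    arrays = {
        "weights": model.weights,
        "alphas": model.alphas,
        "pruned": model.pruned.astype(np.int8),
    }
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_std"] = model.feature_std
    meta = {
        "vocabulary": list(model.vocabulary),
        "n_learners": len(model.learners),
        "meta": model.meta,
        "learner_kernels": [],
    }
    for i, ln in enumerate(model.learners):
        arrays[f"learner{i}_X"] = ln.X_train
        arrays[f"learner{i}_F"] = ln.F_hat
        arrays[f"learner{i}_sigma"] = ln.sigma_blocks
        arrays[f"learner{i}_Kgp"] = ln.term_cov.matrix
        meta["learner_kernels"].append(
            {"lengthscale": ln.kernel.lengthscale,
             "variance": ln.kernel.variance,
             "softmax_mode": ln.softmax_mode}
        )
    arrays["_meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_ensemble(path) -> EnsembleModel:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["_meta_json"]).decode("utf-8"))
        learners = []
        for i in range(meta["n_learners"]):
            km = meta["learner_kernels"][i]
            kernel = InstanceKernel(lengthscale=km["lengthscale"], variance=km["variance"])
            X = z[f"learner{i}_X"]
            from .miml_gp import JITTER
            K = kernel.gram(X) + JITTER * np.eye(len(X))
            learners.append(
                BaseLearner(
                    term_cov=TermCovariance(z[f"learner{i}_Kgp"]),
                    kernel=kernel,
                    X_train=X,
                    F_hat=z[f"learner{i}_F"],
                    K_chol=cho_factor(K, lower=True),
                    sigma_blocks=z[f"learner{i}_sigma"],
                    softmax_mode=km["softmax_mode"],
                )
            )
        return EnsembleModel(
            learners=learners,
            weights=z["weights"],
            alphas=z["alphas"],
            pruned=z["pruned"].astype(bool),
            feature_mean=z["feature_mean"] if "feature_mean" in z else None,
            feature_std=z["feature_std"] if "feature_std" in z else None,
            vocabulary=tuple(meta["vocabulary"]),
            meta=meta.get("meta", {}),
        )
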