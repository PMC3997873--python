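"""Multilabel evaluation: per-term accuracy and ranking losses.

Annotation quality is scored two ways.  Per term, the 0.5-threshold decision
("annotate iff probability >= 0.5") is compared against truth with zero-one
loss.  Across terms, four standard multilabel criteria summarize the full
probability ranking of each bag — all are losses, smaller is better:

* hamming loss — fraction of (bag, term) decisions that disagree with truth;
* one-error — fraction of bags whose top-ranked term is not a true term;
* coverage — how far down the ranking one must go to cover every true term
  (0-based: worst rank of a true term);
* ranking loss — fraction of (true, false) term pairs ranked in the wrong
  order, ties counted as misordered.

Ties in the ranking are broken by term index (earlier index ranks higher).
Bags with an empty or full truth set are excluded from one-error, coverage
and ranking loss, whose denominators are undefined there; hamming loss uses
every bag.

A seeded iterative stratification routine produces train/test splits that
preserve each term's occurrence ratio, emulating a 3:7 stratified protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import TermVector


@dataclass
class PredictionSet:
    """Probabilities and ground truth for a set of bags."""

    bag_ids: list[str]
    prob_matrix: np.ndarray   # (n, s) in [0, 1]
    truth: np.ndarray         # (n, s) binary

    def __post_init__(self) -> None:
        p = np.asarray(self.prob_matrix, dtype=float)
        t = np.asarray(self.truth, dtype=int)
        if p.shape != t.shape or p.ndim != 2:
            raise ValueError("prob_matrix and truth must share an (n, s) shape")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isin(t, (0, 1)).all():
            raise ValueError("truth must be binary")
        if len(self.bag_ids) != p.shape[0]:
            raise ValueError("bag_ids length must match the matrices")
        self.prob_matrix = p
        self.truth = t


def binarize(prob_matrix, threshold: float = 0.5) -> np.ndarray:
    """Decision matrix: 1 iff probability is *not less than* the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(prob_matrix, dtype=float) >= threshold).astype(int)


def per_term_accuracy(preds: PredictionSet, threshold: float = 0.5) -> np.ndarray:
    """Zero-one accuracy of the thresholded decision, term by term."""
    if preds.prob_matrix.shape[0] < 1:
        raise ValueError("need at least one bag")
    dec = binarize(preds.prob_matrix, threshold)
    return (dec == preds.truth).mean(axis=0)


def _ranking(probs: np.ndarray) -> np.ndarray:
    """Rank (0 = highest) of each term; ties broken by smaller term index."""
    order = np.lexsort((np.arange(len(probs)), -probs))
    ranks = np.empty(len(probs), dtype=int)
    ranks[order] = np.arange(len(probs))
    return ranks


def multilabel_metrics(preds: PredictionSet, threshold: float = 0.5) -> dict:
    """The four ranking/decision losses: hloss, one_error, coverage, rloss."""
    n, s = preds.prob_matrix.shape
    if n == 0:
        raise ValueError("need at least one bag")
    dec = binarize(preds.prob_matrix, threshold)
    hloss = float((dec != preds.truth).mean())

    one_err, cov, rloss = [], [], []
    for j in range(n):
        truth = preds.truth[j].astype(bool)
        n_true = int(truth.sum())
        if n_true == 0 or n_true == s:
            continue
        probs = preds.prob_matrix[j]
        ranks = _ranking(probs)
        top = int(np.argmin(ranks))
        one_err.append(0.0 if truth[top] else 1.0)
        cov.append(float(ranks[truth].max()))
        # ranking loss: (true, false) pairs where the false term is ranked
        # at least as high; the tie rule is encoded in the ranks already
        bad = 0
        for t in np.flatnonzero(truth):
            for f in np.flatnonzero(~truth):
                if ranks[f] < ranks[t] or probs[f] == probs[t]:
                    bad += 1
        rloss.append(bad / (n_true * (s - n_true)))

    def _mean(vals):
        return float(np.mean(vals)) if vals else 0.0

    return {
        "hloss": hloss,
        "one_error": _mean(one_err),
        "coverage": _mean(cov),
        "rloss": _mean(rloss),
    }


def stratified_split(
    labels: list[TermVector],
    train_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative-stratification train/test split over multilabel data.

    Greedily assigns examples term by term — rarest term first — so each
    term's occurrence ratio in the train split tracks its global ratio;
    returns disjoint, exhaustive index arrays (train, test).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    Y = np.array([lv.bits for lv in labels], dtype=int)
    n, s = Y.shape
    n_train = int(round(train_fraction * n))

    desired = {"train": Y.sum(axis=0) * train_fraction,
               "test": Y.sum(axis=0) * (1.0 - train_fraction)}
    capacity = {"train": n_train, "test": n - n_train}
    assigned = np.full(n, "", dtype=object)
    remaining = np.ones(n, dtype=bool)

    while remaining.any():
        candidates = np.flatnonzero(remaining)
        rem_pos = Y[candidates].sum(axis=0)
        if rem_pos.max() == 0:
            t, pool = None, candidates  # label-free leftovers: fill capacity
        else:
            positive_terms = np.flatnonzero(rem_pos > 0)
            t = int(positive_terms[np.argmin(rem_pos[positive_terms])])
            pool = candidates[Y[candidates, t] == 1]
        for j in rng.permutation(pool):
            scores = {}
            for side in ("train", "test"):
                if capacity[side] <= 0:
                    scores[side] = (-np.inf, -np.inf)
                    continue
                need = desired[side][t] if t is not None else float(capacity[side])
                scores[side] = (need, capacity[side])
            side = max(scores, key=lambda kk: scores[kk])
            if capacity[side] <= 0:
                side = "train" if capacity["train"] > 0 else "test"
            assigned[j] = side
            remaining[j] = False
            capacity[side] -= 1
            for tt in np.flatnonzero(Y[j]):
                desired[side][tt] -= 1

    train_ids = np.flatnonzero(assigned == "train")
    test_ids = np.flatnonzero(assigned == "test")
    return train_ids, test_ids


def evaluate_predictions(
    bag_ids, prob_matrix, truth, threshold: float = 0.5
) -> dict:
    """Bundle per-term accuracy and the four multilabel losses into one dict."""
    preds = PredictionSet(list(bag_ids), prob_matrix, truth)
    out = multilabel_metrics(preds, threshold)
    out["per_term_accuracy"] = per_term_accuracy(preds, threshold).tolist()
    return out
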