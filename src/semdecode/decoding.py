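"""Ridge decoding of word vectors from EEG features and the 2 vs. 2 test.

A bank of per-dimension ridge regressions maps flattened EEG features to word
vectors.  Decoding quality is measured leave-two-out: for every unordered pair
of symbols the model is refit on the remaining rows, the two held-out vectors
are predicted, and the pair passes when the summed cosine distances of the
correctly matched true/predicted vectors beat the mismatched assignment.
Chance is 50%.

Because each held-out prediction is a linear functional of the training
targets, the evaluator precomputes one prediction operator per pair from the
feature Gram matrix; evaluating a new target matrix (e.g., a permutation
shuffle) then costs a single matrix product.  This reproduces naive
refitting exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .epochs import DesignMatrix
from .generate import WordVectors

__all__ = [
    "RidgeModel",
    "TwoVsTwoResult",
    "fit_ridge",
    "predict",
    "two_vs_two_pair",
    "PairwiseDecoder",
    "evaluate_loto",
]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DesignMatrix):
        X = X.X
    return np.asarray(X, dtype=np.float64)


def _as_targets(Y) -> np.ndarray:
    if isinstance(Y, WordVectors):
        Y = Y.Y
    return np.asarray(Y, dtype=np.float64)


@dataclass
class RidgeModel:
    """Closed-form L2-regularized linear map from features to word vectors.

    Trained with column centering of both X and Y in lieu of an intercept;
    ``weights`` has one column per embedding dimension.
    """

    weights: np.ndarray
    alpha: float
    x_center: np.ndarray
    y_center: np.ndarray


def fit_ridge(X, Y, alpha: float = 0.1, center: bool = True) -> RidgeModel:
    """Solve ``min_W ||Xc W - Yc||^2 + alpha ||W||^2`` in closed form.

    Uses the primal normal equations when features <= samples and the
    equivalent dual (Gram) formulation otherwise; the two agree for any
    alpha > 0.
    """
    X = _as_matrix(X)
    Y = _as_targets(Y)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in inputs")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have aligned rows")

    n, d = X.shape
    if center:
        x_center = X.mean(axis=0)
        y_center = Y.mean(axis=0)
    else:
        x_center = np.zeros(d)
        y_center = np.zeros(Y.shape[1])
    Xc = X - x_center
    Yc = Y - y_center

    if d <= n:
        A = Xc.T @ Xc + alpha * np.eye(d)
        W = np.linalg.solve(A, Xc.T @ Yc)
    else:
        K = Xc @ Xc.T + alpha * np.eye(n)
        W = Xc.T @ np.linalg.solve(K, Yc)
    return RidgeModel(weights=W, alpha=alpha, x_center=x_center, y_center=y_center)


def predict(model: RidgeModel, X_new) -> np.ndarray:
    """Predicted word vectors for new feature rows."""
    X_new = _as_matrix(X_new)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match the "
            f"{model.weights.shape[0]} training features"
        )
    return (X_new - model.x_center) @ model.weights + model.y_center


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero-norm vector in cosine distance; using d = 1", stacklevel=3)
        return 1.0
    return 1.0 - float(u @ v) / (nu * nv)


def two_vs_two_pair(y_i, y_j, yhat_i, yhat_j) -> float:
    """Score one leave-two-out pair: 1 (pass), 0 (fail), or 0.5 (exact tie).

    Passes when the matched cosine distances d(y_i, ŷ_i) + d(y_j, ŷ_j) are
    smaller than the mismatched d(y_i, ŷ_j) + d(y_j, ŷ_i).
    """
    vecs = [np.asarray(v, dtype=np.float64).ravel() for v in (y_i, y_j, yhat_i, yhat_j)]
    if len({v.shape for v in vecs}) != 1:
        raise ValueError("all four vectors must share one dimension")
    y_i, y_j, yhat_i, yhat_j = vecs
    matched = _cosine_distance(y_i, yhat_i) + _cosine_distance(y_j, yhat_j)
    mismatched = _cosine_distance(y_i, yhat_j) + _cosine_distance(y_j, yhat_i)
    if matched < mismatched:
        return 1.0
    if matched > mismatched:
        return 0.0
    return 0.5


@dataclass
class TwoVsTwoResult:
    """Outcome of the 2 vs. 2 evaluation over all symbol pairs."""

    outcomes: np.ndarray  # (n_pairs,) values in {0, 0.5, 1}
    pairs: np.ndarray  # (n_pairs, 2) row indices
    predictions: np.ndarray | None = None  # (n_pairs, 2, v) held-out predictions
    matched_distance: np.ndarray | None = None
    mismatched_distance: np.ndarray | None = None

    @property
    def accuracy(self) -> float:
        return float(self.outcomes.mean())

    @property
    def n_pairs(self) -> int:
        return self.outcomes.size

    def outcome_matrix(self, n: int) -> np.ndarray:
        """Symmetric (n, n) matrix of pair outcomes (nan on the diagonal)."""
        O = np.full((n, n), np.nan)
        O[self.pairs[:, 0], self.pairs[:, 1]] = self.outcomes
        O[self.pairs[:, 1], self.pairs[:, 0]] = self.outcomes
        return O


class PairwiseDecoder:
    """Gram-cached leave-two-out ridge evaluator.

    For every pair (i, j) the held-out predictions under training-mean
    centering are ŷ_t = g_t^T Y_S (t in {i, j}), where g_t depends only on
    the feature Gram matrix and alpha.  The operators are assembled once;
    ``evaluate`` then scores any target matrix with one matrix product,
    which makes permutation shuffles of Y essentially free.
    """

    def __init__(self, X, alpha: float = 0.1):
        X = _as_matrix(X)
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in X")
        ns = X.shape[0]
        if ns < 3:
            raise ValueError("need at least 3 rows for leave-two-out evaluation")
        self.alpha = float(alpha)
        self.n_rows = ns
        self.pairs = np.array(list(combinations(range(ns), 2)), dtype=np.intp)

        K = X @ X.T
        rowsum = K.sum(axis=1)
        total = float(K.sum())
        all_idx = np.arange(ns)

        G = np.zeros((len(self.pairs), 2, ns))
        n = ns - 2
        for p, (i, j) in enumerate(self.pairs):
            S = np.delete(all_idx, [i, j])
            # sums over the training subset
            sub_rowsum = rowsum[S] - K[S, i] - K[S, j]
            sub_total = (
                total
                - 2.0 * (rowsum[i] + rowsum[j])
                + K[i, i] + 2.0 * K[i, j] + K[j, j]
            )
            # double-centered training Gram
            Kc = (
                K[np.ix_(S, S)]
                - sub_rowsum[None, :] / n
                - sub_rowsum[:, None] / n
                + sub_total / n**2
            )
            A = Kc + self.alpha * np.eye(n)
            for t_slot, t in enumerate((i, j)):
                t_rowsum = rowsum[t] - K[t, i] - K[t, j]
                c_t = K[t, S] - t_rowsum / n - sub_rowsum / n + sub_total / n**2
                w = np.linalg.solve(A, c_t)
                g = w + (1.0 - w.sum()) / n
                G[p, t_slot, S] = g
        self._G = G.reshape(len(self.pairs) * 2, ns)

    def evaluate(self, Y, keep_predictions: bool = False) -> TwoVsTwoResult:
        """Score a target matrix over all pairs with the cached operators."""
        Y = _as_targets(Y)
        if Y.shape[0] != self.n_rows:
            raise ValueError("Y row count must match the design matrix")
        preds = (self._G @ Y).reshape(len(self.pairs), 2, Y.shape[1])
        yi = Y[self.pairs[:, 0]]
        yj = Y[self.pairs[:, 1]]

        def dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            denom = na * nb
            zero = denom == 0
            if zero.any():
                warnings.warn("zero-norm vector in cosine distance; using d = 1", stacklevel=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = 1.0 - np.einsum("ij,ij->i", a, b) / denom
            d[zero] = 1.0
            return d

        matched = dists(yi, preds[:, 0]) + dists(yj, preds[:, 1])
        mismatched = dists(yi, preds[:, 1]) + dists(yj, preds[:, 0])
        outcomes = np.where(matched < mismatched, 1.0, np.where(matched > mismatched, 0.0, 0.5))
        return TwoVsTwoResult(
            outcomes=outcomes,
            pairs=self.pairs.copy(),
            predictions=preds if keep_predictions else None,
            matched_distance=matched,
            mismatched_distance=mismatched,
        )


    def evaluate_accuracies(self, Y, perms: np.ndarray, chunk: int = 50) -> np.ndarray:
        """Accuracies for many row shuffles of Y at once.

        Equivalent to ``[self.evaluate(Y[p]).accuracy for p in perms]`` but
        batched into a few large matrix products (chunked to bound memory).
        """
        Y = _as_targets(Y)
        perms = np.asarray(perms)
        accs = np.empty(perms.shape[0])
        i0, j0 = self.pairs[:, 0], self.pairs[:, 1]
        for lo in range(0, perms.shape[0], chunk):
            block = perms[lo : lo + chunk]
            Yp = Y[block]  # (B, ns, v)
            preds = np.tensordot(self._G, Yp, axes=([1], [1]))  # (2P, B, v)
            preds = preds.reshape(len(self.pairs), 2, block.shape[0], -1)
            yi = Yp[:, i0, :].transpose(1, 0, 2)  # (P, B, v)
            yj = Yp[:, j0, :].transpose(1, 0, 2)

            def dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
                na = np.linalg.norm(a, axis=-1)
                nb = np.linalg.norm(b, axis=-1)
                denom = na * nb
                with np.errstate(invalid="ignore", divide="ignore"):
                    d = 1.0 - np.einsum("pbv,pbv->pb", a, b) / denom
                d[denom == 0] = 1.0
                return d

            matched = dists(yi, preds[:, 0]) + dists(yj, preds[:, 1])
            mismatched = dists(yi, preds[:, 1]) + dists(yj, preds[:, 0])
            out = np.where(matched < mismatched, 1.0, np.where(matched > mismatched, 0.0, 0.5))
            accs[lo : lo + block.shape[0]] = out.mean(axis=0)
        return accs


def evaluate_loto(X, Y, alpha: float = 0.1, keep_predictions: bool = False) -> TwoVsTwoResult:
    """Leave-two-out 2 vs. 2 evaluation over all C(ns, 2) symbol pairs."""
    return PairwiseDecoder(X, alpha=alpha).evaluate(Y, keep_predictions=keep_predictions)
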