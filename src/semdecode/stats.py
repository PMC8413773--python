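"""Inference for 2 vs. 2 accuracies: permutation tests, BY-FDR correction,
and symbol-level bootstrap comparison of two conditions.

The permutation null shuffles the symbol-to-word-vector assignment and reruns
the full leave-two-out evaluation; because the cached pair operators depend
only on the EEG features, every shuffle costs a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decoding import PairwiseDecoder, TwoVsTwoResult, _as_targets

__all__ = [
    "PermutationResult",
    "BootstrapComparison",
    "draw_permutations",
    "permutation_test",
    "permutation_pvalue",
    "fdr_bhy",
    "bootstrap_accuracy_diff",
]


@dataclass
class PermutationResult:
    """Observed accuracy against a shuffled-assignment null distribution."""

    observed: float
    null_accuracies: np.ndarray
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.null_accuracies.size

    @property
    def p_value(self) -> float:
        # add-one rule: never exactly zero, valid at any n_perm
        return (1 + int(np.sum(self.null_accuracies >= self.observed))) / (1 + self.n_perm)

    def to_dict(self) -> dict:
        nulls = self.null_accuracies
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "null_mean": float(nulls.mean()),
            "null_sd": float(nulls.std(ddof=1)) if self.n_perm > 1 else 0.0,
            "null_q05": float(np.quantile(nulls, 0.05)),
            "null_q95": float(np.quantile(nulls, 0.95)),
            "seed": self.seed,
        }


def draw_permutations(n_rows: int, n_perm: int, seed: int) -> np.ndarray:
    """Draw ``n_perm`` row shuffles; shareable across analyses for
    comparable nulls (e.g., all searchlight groups)."""
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n_rows) for _ in range(n_perm)])


def permutation_pvalue(
    decoder: PairwiseDecoder, Y, perms: np.ndarray, observed: float | None = None, seed: int | None = None
) -> PermutationResult:
    """Permutation test against precomputed shuffles using a cached decoder."""
    Y = _as_targets(Y)
    if observed is None:
        observed = decoder.evaluate(Y).accuracy
    nulls = decoder.evaluate_accuracies(Y, perms)
    return PermutationResult(observed=observed, null_accuracies=nulls, seed=seed)


def permutation_test(X, Y, alpha: float = 0.1, n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Shuffle the symbol-to-vector row assignment and recompute the full
    leave-two-out 2 vs. 2 accuracy for each of ``n_perm`` shuffles."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    decoder = PairwiseDecoder(X, alpha=alpha)
    Y = _as_targets(Y)
    perms = draw_permutations(Y.shape[0], n_perm, seed)
    return permutation_pvalue(decoder, Y, perms, seed=seed)


def fdr_bhy(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg–Yekutieli step-up rejection mask.

    Valid under arbitrary dependence via the harmonic correction
    c(m) = sum_{i=1..m} 1/i: reject the k smallest p-values where k is the
    largest i with p_(i) <= i * alpha / (m * c(m)).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_by")
    return reject


@dataclass
class BootstrapComparison:
    """Normal-theory bootstrap comparison of two 2 vs. 2 accuracies.

    Symbols are the resampling unit: each replicate redraws symbols with
    replacement and averages the cached pair outcomes over the pairs of
    distinct resampled symbols, for both conditions.
    """

    accuracy_a: float
    accuracy_b: float
    difference: float  # b - a
    replicates: np.ndarray
    seed: int | None = None

    @property
    def sd_boot(self) -> float:
        return float(self.replicates.std(ddof=1))

    @property
    def ci95(self) -> tuple[float, float]:
        z = sps.norm.ppf(0.975)
        return (self.difference - z * self.sd_boot, self.difference + z * self.sd_boot)

    @property
    def p_value(self) -> float:
        sd = self.sd_boot
        if sd == 0:
            return 1.0 if self.difference == 0 else 0.0
        return float(2 * sps.norm.sf(abs(self.difference) / sd))

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "accuracy_a": self.accuracy_a,
            "accuracy_b": self.accuracy_b,
            "difference": self.difference,
            "sd_boot": self.sd_boot,
            "ci95": [lo, hi],
            "p_value": self.p_value,
            "n_boot": int(self.replicates.size),
            "seed": self.seed,
        }


def _resampled_accuracy(O: np.ndarray, idx: np.ndarray) -> float:
    sub = O[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    distinct = idx[iu] != idx[ju]
    vals = sub[iu[distinct], ju[distinct]]
    return float(vals.mean())


def bootstrap_accuracy_diff(
    result_a: TwoVsTwoResult,
    result_b: TwoVsTwoResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap the accuracy difference (condition B minus condition A).

    Both results must cover the same symbols in the same order.  Replicates
    with fewer than 3 distinct resampled symbols are redrawn.
    """
    if result_a.n_pairs != result_b.n_pairs:
        raise ValueError("conditions must share the same symbol pairs")
    n = int(result_a.pairs.max()) + 1
    Oa = result_a.outcome_matrix(n)
    Ob = result_b.outcome_matrix(n)
    rng = np.random.default_rng(seed)

    reps = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= 3:
                break
        reps[b] = _resampled_accuracy(Ob, idx) - _resampled_accuracy(Oa, idx)

    return BootstrapComparison(
        accuracy_a=result_a.accuracy,
        accuracy_b=result_b.accuracy,
        difference=result_b.accuracy - result_a.accuracy,
        replicates=reps,
        seed=seed,
    )
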