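"""Epoch preprocessing: trimming, baseline correction, artifact rejection,
trial selection, averaging, and window/electrode selection with flattening.

The pipeline turns a stack of raw single-trial epochs into the design matrix
X (one row per symbol) that the decoder consumes: epochs are trimmed to the
first second after symbol onset, baseline-corrected against the pre-onset
span, screened for amplitude artifacts, filtered by exposure criteria, pooled
into a per-symbol average, optionally restricted in time and space, and
flattened electrode-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import DesignMatrix, EpochCollection, SelectedTensor, WindowSpec

__all__ = [
    "RejectionReport",
    "trim_epochs",
    "baseline_correct",
    "reject_artifacts",
    "select_trials",
    "average_selected",
    "select_window",
    "select_electrodes",
    "flatten",
]


@dataclass
class RejectionReport:
    """Counts from amplitude-based artifact rejection."""

    n_total: int
    n_rejected: int
    n_p2p: int
    n_gradient: int
    p2p_limit_uv: float
    grad_limit_uv_per_ms: float

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_rejected": self.n_rejected,
            "n_p2p": self.n_p2p,
            "n_gradient": self.n_gradient,
            "rejected_fraction": self.rejected_fraction,
            "p2p_limit_uv": self.p2p_limit_uv,
            "grad_limit_uv_per_ms": self.grad_limit_uv_per_ms,
        }


def trim_epochs(epochs: EpochCollection) -> EpochCollection:
    """Keep only the [0, 1000) ms span after symbol onset.

    Idempotent on already-trimmed input.  Errors if the epochs do not cover
    the full first second.
    """
    spec = WindowSpec(0.0, 1000.0)
    idx = spec.sample_indices(epochs.sfreq, epochs.n_samples, epochs.tmin_ms)
    expected = int(round(epochs.sfreq))  # 1 s worth of samples
    if idx.size != expected:
        raise ValueError(
            f"epochs cover only {idx.size} of the {expected} samples in [0, 1000) ms"
        )
    if idx.size == epochs.n_samples:
        return epochs
    return EpochCollection(
        data=epochs.data[:, :, idx],
        meta=epochs.meta.copy(),
        sfreq=epochs.sfreq,
        tmin_ms=0.0,
        electrodes=epochs.electrodes,
    )


def baseline_correct(
    epochs: EpochCollection, baseline: WindowSpec = WindowSpec(-200.0, 0.0)
) -> EpochCollection:
    """Subtract each electrode's mean over the baseline span from every epoch."""
    if epochs.tmin_ms > baseline.start_ms:
        raise ValueError(
            f"baseline span [{baseline.start_ms}, {baseline.end_ms}) ms not present "
            f"in epochs starting at {epochs.tmin_ms} ms"
        )
    idx = baseline.sample_indices(epochs.sfreq, epochs.n_samples, epochs.tmin_ms)
    means = epochs.data[:, :, idx].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - means, meta=epochs.meta.copy())


def reject_artifacts(
    epochs: EpochCollection,
    p2p_limit: float = 100.0,
    grad_limit: float = 10.0,
) -> tuple[EpochCollection, RejectionReport]:
    """Drop epochs violating peak-to-peak or gradient amplitude limits.

    An epoch is rejected iff on ANY electrode (max - min) exceeds
    ``p2p_limit`` microvolts, or any adjacent-sample absolute difference
    exceeds ``grad_limit`` μV/ms times the sample interval.
    """
    data = np.asarray(epochs.data, dtype=np.float64)
    p2p = data.max(axis=2) - data.min(axis=2)  # (epochs, electrodes)
    bad_p2p = (p2p > p2p_limit).any(axis=1)

    step_limit = grad_limit * 1000.0 / epochs.sfreq  # μV allowed per sample step
    steps = np.abs(np.diff(data, axis=2))
    bad_grad = (steps > step_limit).any(axis=(1, 2))

    bad = bad_p2p | bad_grad
    report = RejectionReport(
        n_total=epochs.n_epochs,
        n_rejected=int(bad.sum()),
        n_p2p=int(bad_p2p.sum()),
        n_gradient=int(bad_grad.sum()),
        p2p_limit_uv=p2p_limit,
        grad_limit_uv_per_ms=grad_limit,
    )
    return epochs.subset(~bad), report


def select_trials(
    epochs: EpochCollection,
    min_exposures: int = 6,
    drop_first: int = 2,
    trial_window: tuple[int, int] | None = None,
) -> EpochCollection:
    """Apply exposure-based trial selection.

    Per participant, symbols presented fewer than ``min_exposures`` times are
    excluded entirely; the first ``drop_first`` exposures of each remaining
    symbol are dropped.  If ``trial_window = (a, b)`` is given it replaces
    ``drop_first`` and retains exposures a..b (1-based, inclusive) only.
    Exposure indices count presentations in the original order, so earlier
    artifact rejection cannot shift which trials count as the first ones.
    """
    meta = epochs.meta
    n_pres = meta["n_presentations"].to_numpy()
    exp = meta["exposure_index"].to_numpy()

    keep = n_pres >= min_exposures
    if trial_window is not None:
        a, b = trial_window
        if not (1 <= a <= b):
            raise ValueError("trial_window must satisfy 1 <= a <= b")
        keep &= (exp >= a) & (exp <= b)
    else:
        keep &= exp > drop_first

    before = set(epochs.symbols.tolist())
    out = epochs.subset(keep)
    if out.n_epochs == 0:
        raise ValueError("trial selection excluded every symbol")
    dropped = sorted(before - set(out.symbols.tolist()))
    out.meta.attrs["symbols_removed"] = dropped
    return out


def average_selected(epochs: EpochCollection) -> SelectedTensor:
    """Pool all selected trials of all participants into one mean per symbol.

    Every trial has weight one (trial-pooled, not a mean of participant
    means), matching an equal-weight average across all selected trials and
    participants.
    """
    symbols = epochs.symbols
    sym_col = epochs.meta["symbol"].to_numpy()
    out = np.empty((symbols.size, epochs.n_electrodes, epochs.n_samples))
    for i, s in enumerate(symbols):
        out[i] = np.asarray(epochs.data[sym_col == s], dtype=np.float64).mean(axis=0)
    return SelectedTensor(
        data=out,
        symbols=symbols,
        electrodes=epochs.electrodes,
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
        provenance={
            "n_trials": int(epochs.n_epochs),
            "participants": [int(p) for p in epochs.participants],
        },
    )


def select_window(t: SelectedTensor, w: WindowSpec) -> SelectedTensor:
    """Restrict the tensor to the samples whose times fall in the window."""
    idx = w.sample_indices(t.sfreq, t.data.shape[2], t.tmin_ms)
    prov = dict(t.provenance)
    prov["window_ms"] = (w.start_ms, w.end_ms)
    return SelectedTensor(
        data=t.data[:, :, idx],
        symbols=t.symbols,
        electrodes=t.electrodes,
        sfreq=t.sfreq,
        tmin_ms=float(t.tmin_ms + idx[0] * 1000.0 / t.sfreq),
        provenance=prov,
    )


def select_electrodes(t: SelectedTensor, group: list[str]) -> SelectedTensor:
    """Restrict the tensor to the named electrodes (order preserved as given)."""
    missing = [e for e in group if e not in t.electrodes]
    if missing:
        raise ValueError(f"electrodes not in tensor: {missing}")
    if not group:
        raise ValueError("empty electrode selection")
    idx = [t.electrodes.index(e) for e in group]
    prov = dict(t.provenance)
    prov["electrodes"] = list(group)
    return SelectedTensor(
        data=t.data[:, idx, :],
        symbols=t.symbols,
        electrodes=tuple(group),
        sfreq=t.sfreq,
        tmin_ms=t.tmin_ms,
        provenance=prov,
    )


def flatten(t: SelectedTensor) -> DesignMatrix:
    """Reshape (ns, ne, l) to (ns, ne*l), electrode-major and time-minor."""
    ns, ne, l = t.data.shape
    names = tuple(f"{e}:{k}" for e in t.electrodes for k in range(l))
    return DesignMatrix(X=t.data.reshape(ns, ne * l), symbols=t.symbols, feature_names=names)
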