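"""In-memory containers for epoched EEG and derived analysis tensors."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["EpochCollection", "SelectedTensor", "WindowSpec", "DesignMatrix"]

#: metadata columns every EpochCollection carries, one row per epoch
META_COLUMNS = (
    "participant",
    "symbol",
    "exposure_index",
    "n_presentations",
    "signal_present",
    "artifact_injected",
)


@dataclass
class EpochCollection:
    """A stack of single-trial EEG epochs with per-epoch metadata.

    data is (n_epochs, n_electrodes, n_samples) in microvolts; sample k of an
    epoch is at time ``tmin_ms + k * 1000 / sfreq`` relative to symbol onset.
    ``meta`` has one row per epoch (participant, symbol, exposure_index,
    n_presentations, signal_present, artifact_injected).
    """

    data: np.ndarray
    meta: pd.DataFrame
    sfreq: float
    tmin_ms: float
    electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs, electrodes, samples)")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("metadata rows must match the number of epochs")
        if self.data.shape[1] != len(self.electrodes):
            raise ValueError(
                f"{len(self.electrodes)} electrode names for "
                f"{self.data.shape[1]} data channels"
            )
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    @property
    def participants(self) -> np.ndarray:
        return np.unique(self.meta["participant"].to_numpy())

    @property
    def symbols(self) -> np.ndarray:
        return np.unique(self.meta["symbol"].to_numpy())

    def subset(self, mask: np.ndarray) -> "EpochCollection":
        """New collection containing the epochs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return EpochCollection(
            data=self.data[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            electrodes=self.electrodes,
        )

    def copy_with(self, **kwargs: Any) -> "EpochCollection":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window [start_ms, end_ms) mapped onto sample indices.

    Sample k (at time tmin + k/fs) is included iff its time lies in the
    window; this keeps adjacent sliding windows partition-consistent even
    when the window length is not an integer number of samples.
    """

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise ValueError("window end must exceed start")

    def sample_indices(self, sfreq: float, n_samples: int, tmin_ms: float = 0.0) -> np.ndarray:
        times = tmin_ms + np.arange(n_samples) * 1000.0 / sfreq
        idx = np.nonzero((times >= self.start_ms) & (times < self.end_ms))[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{self.start_ms}, {self.end_ms}) ms selects no samples "
                f"at {sfreq} Hz"
            )
        return idx


@dataclass
class SelectedTensor:
    """Symbol-averaged tensor (n_symbols, n_electrodes, n_samples), microvolts."""

    data: np.ndarray
    symbols: np.ndarray  # symbol ids aligned to axis 0
    electrodes: tuple[str, ...]
    sfreq: float
    tmin_ms: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.symbols = np.asarray(self.symbols)
        if self.data.ndim != 3:
            raise ValueError("selected tensor must be 3-D")
        if self.data.shape[0] != self.symbols.size:
            raise ValueError("symbol axis mismatch")
        if self.data.shape[1] != len(self.electrodes):
            raise ValueError("electrode axis mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("selected tensor contains non-finite values")

    @property
    def n_symbols(self) -> int:
        return self.data.shape[0]


@dataclass
class DesignMatrix:
    """Flattened features X (n_symbols, n_electrodes * n_samples).

    Feature order is electrode-major, time-minor: column e * n_samples + k
    holds electrode e at sample k.
    """

    X: np.ndarray
    symbols: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.X.shape[0] != np.asarray(self.symbols).size:
            raise ValueError("row count must match symbol count")

    @property
    def n_symbols(self) -> int:
        return self.X.shape[0]
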