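"""Synthetic word vectors and epoched EEG with a planted linear semantic signal.

The generator emulates the learning experiment end to end: behavioral trials
come from :mod:`semdecode.paradigm`; each trial's epoch is per-electrode AR(1)
noise plus, on trials where the simulated learner has already acquired the
symbol's word, a planted signal ``gain * g(t) * (M @ y_s)`` — a fixed
electrode mixing of the symbol's word vector modulated by a temporal envelope.
Occasional trials get an injected high-amplitude artifact guaranteed to
violate the downstream rejection thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .epochs import EpochCollection
from .paradigm import LearnerModel, ParadigmConfig, TrialRecord, build_schedule, simulate_behavior

__all__ = [
    "WordVectors",
    "ForwardModel",
    "generate_word_vectors",
    "generate_eeg_epochs",
    "simulate_dataset",
]


@dataclass
class WordVectors:
    """Word-embedding targets Y: one row per symbol's mapped word."""

    Y: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim != 2:
            raise ValueError("word vectors must form a 2-D matrix")
        if self.Y.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("word labels must be unique")
        norms = np.linalg.norm(self.Y, axis=1)
        if np.any(norms == 0):
            raise ValueError("word vectors may not contain all-zero rows")

    @property
    def n_words(self) -> int:
        return self.Y.shape[0]

    @property
    def dim(self) -> int:
        return self.Y.shape[1]


@dataclass
class ForwardModel:
    """Maps word vectors to electrode-space signal and sets the noise model.

    * ``mixing`` M (n_electrodes, v): spatial pattern per embedding dimension.
      If None, drawn N(0, 1/v) at generation so that (M @ y) has unit-order
      amplitude for standard-normal word vectors.
    * envelope: nonnegative weights g(t), max 1, supported on
      [envelope_on_ms, envelope_off_ms) — a Hann bump by default.
    * gain: signal amplitude in microvolts at the envelope peak (SNR control).
    * AR(1) noise per electrode: x_t = ar_coef * x_{t-1} + e_t with
      innovation scale chosen so the stationary standard deviation is
      ``noise_sd`` microvolts.
    * artifact_rate: per-trial probability of an injected artifact (a large
      single-sample spike violating both peak-to-peak and gradient limits).
    * participant_jitter: relative sd of multiplicative per-participant noise
      on M, emulating inter-participant variability in topography.
    * electrode_subset: if given, mixing is confined to these electrode
      indices (rows of M outside the subset are zeroed) — used to plant a
      spatially localized signal.
    """

    gain: float = 1.0
    envelope_on_ms: float = 150.0
    envelope_off_ms: float = 650.0
    ar_coef: float = 0.95
    noise_sd: float = 10.0
    artifact_rate: float = 0.0
    participant_jitter: float = 0.1
    mixing: np.ndarray | None = None
    electrode_subset: tuple[int, ...] | None = None
    artifact_amplitude_uv: float = 500.0

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        g = np.zeros_like(times_ms, dtype=np.float64)
        on, off = self.envelope_on_ms, self.envelope_off_ms
        inside = (times_ms >= on) & (times_ms < off)
        if inside.any():
            phase = (times_ms[inside] - on) / (off - on)
            g[inside] = np.sin(np.pi * phase) ** 2
            peak = g.max()
            if peak > 0:
                g /= peak
        return g


def generate_word_vectors(
    ns: int,
    v: int = 50,
    seed: int = 0,
    normalize: bool = False,
    labels: tuple[str, ...] | None = None,
) -> WordVectors:
    """I.i.d. standard-normal word vectors; optionally row-normalized."""
    if ns < 3:
        raise ValueError("need at least 3 words")
    if v < 2:
        raise ValueError("need at least 2 dimensions")
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((ns, v))
    if normalize:
        Y /= np.linalg.norm(Y, axis=1, keepdims=True)
    if labels is None:
        labels = tuple(f"word{i:03d}" for i in range(ns))
    return WordVectors(Y=Y, labels=labels)


def generate_eeg_epochs(
    trials: list[TrialRecord],
    vectors: WordVectors,
    fwd: ForwardModel,
    n_electrodes: int = 32,
    n_samples: int = 250,
    sampling_rate: float = 250.0,
    seed: int = 0,
    tmin_ms: float = 0.0,
    electrodes: tuple[str, ...] | None = None,
) -> EpochCollection:
    """Generate one epoch per trial: AR(1) noise + planted signal + artifacts.

    The planted signal appears only on trials whose ``acquired_before_trial``
    flag is set; ground truth (signal_present, artifact_injected) is stored in
    the epoch metadata.  Byte-identical given the same seed.
    """
    rng = np.random.default_rng(seed)
    missing = sorted({t.symbol for t in trials} - set(range(vectors.n_words)))
    if missing:
        raise ValueError(f"no word vector row for symbol(s): {missing}")

    if electrodes is None:
        electrodes = tuple(f"E{i:02d}" for i in range(n_electrodes))
    if len(electrodes) != n_electrodes:
        raise ValueError("electrode name count must match n_electrodes")

    times = tmin_ms + np.arange(n_samples) * 1000.0 / sampling_rate
    g = fwd.envelope(times)

    if fwd.mixing is None:
        M = rng.standard_normal((n_electrodes, vectors.dim)) / np.sqrt(vectors.dim)
    else:
        M = np.asarray(fwd.mixing, dtype=np.float64)
        if M.shape != (n_electrodes, vectors.dim):
            raise ValueError("mixing matrix shape must be (n_electrodes, v)")
        M = M.copy()
    if fwd.electrode_subset is not None:
        keep = np.zeros(n_electrodes, dtype=bool)
        keep[list(fwd.electrode_subset)] = True
        M[~keep] = 0.0

    # per-participant multiplicative jitter on the mixing matrix
    participants = sorted({t.participant for t in trials})
    M_per_p = {}
    for p in participants:
        jitter = 1.0 + fwd.participant_jitter * rng.standard_normal(M.shape)
        M_per_p[p] = M * jitter

    n_trials = len(trials)
    innovation_sd = fwd.noise_sd * np.sqrt(1.0 - fwd.ar_coef**2)
    white = rng.standard_normal((n_trials, n_electrodes, n_samples)) * innovation_sd
    data = lfilter([1.0], [1.0, -fwd.ar_coef], white, axis=-1)

    signal_present = np.zeros(n_trials, dtype=bool)
    artifact_injected = rng.random(n_trials) < fwd.artifact_rate

    for i, t in enumerate(trials):
        if t.acquired_before_trial and fwd.gain != 0.0:
            pattern = M_per_p[t.participant] @ vectors.Y[t.symbol]
            data[i] += fwd.gain * np.outer(pattern, g)
            signal_present[i] = True
        if artifact_injected[i]:
            e = int(rng.integers(n_electrodes))
            k = int(rng.integers(1, n_samples))
            data[i, e, k] += fwd.artifact_amplitude_uv

    n_pres = {}
    for t in trials:
        key = (t.participant, t.symbol)
        n_pres[key] = max(n_pres.get(key, 0), t.exposure_index)
    meta = pd.DataFrame(
        {
            "participant": [t.participant for t in trials],
            "symbol": [t.symbol for t in trials],
            "exposure_index": [t.exposure_index for t in trials],
            "n_presentations": [n_pres[(t.participant, t.symbol)] for t in trials],
            "signal_present": signal_present,
            "artifact_injected": artifact_injected,
        }
    )
    return EpochCollection(
        data=data.astype(np.float32),
        meta=meta,
        sfreq=sampling_rate,
        tmin_ms=tmin_ms,
        electrodes=electrodes,
    )


def simulate_dataset(
    seed: int,
    config: ParadigmConfig | None = None,
    learner: LearnerModel | None = None,
    fwd: ForwardModel | None = None,
    n_participants: int = 25,
    n_electrodes: int = 32,
    n_samples: int = 250,
    sampling_rate: float = 250.0,
    vector_dim: int = 50,
    tmin_ms: float = 0.0,
    electrodes: tuple[str, ...] | None = None,
) -> tuple[EpochCollection, WordVectors, list[TrialRecord]]:
    """Simulate a full multi-participant experiment.

    One shared schedule-free design: every participant gets an independent
    block schedule and behavioral run (seeds derived from ``seed``), while
    the word vectors, mixing matrix, and symbol→word lexicon are common.
    """
    config = config or ParadigmConfig()
    learner = learner or LearnerModel()
    fwd = fwd or ForwardModel()
    rng = np.random.default_rng(seed)
    vec_seed, eeg_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    vectors = generate_word_vectors(config.n_symbols, vector_dim, seed=vec_seed)
    all_trials: list[TrialRecord] = []
    for p in range(n_participants):
        s_sched, s_beh = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        schedule = build_schedule(config, seed=s_sched)
        all_trials.extend(simulate_behavior(schedule, config, learner, seed=s_beh, participant=p))

    epochs = generate_eeg_epochs(
        all_trials,
        vectors,
        fwd,
        n_electrodes=n_electrodes,
        n_samples=n_samples,
        sampling_rate=sampling_rate,
        seed=eeg_seed,
        tmin_ms=tmin_ms,
        electrodes=electrodes,
    )
    return epochs, vectors, all_trials
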