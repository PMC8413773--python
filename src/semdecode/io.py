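"""File formats and run configuration.

Epochs are stored in a documented HDF5 layout::

    /participants/<id>/symbols/<id>/epochs   (r, n_electrodes, l) float32, μV
        attrs: exposure_indices, n_presentations, signal_present,
               artifact_injected
    root attrs: schema_version, electrodes, sfreq, tmin_ms

Word vectors use the word2vec text dialect (header "count dim", then one
"label value value ..." line per word).  Configurations and reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochCollection
from .generate import WordVectors
from .paradigm import ParadigmConfig

__all__ = [
    "GeneratorConfig",
    "AnalysisConfig",
    "RunConfig",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_word_vectors",
    "read_word_vectors",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-data settings (see :class:`semdecode.generate.ForwardModel`)."""

    gain: float = 1.0
    envelope_on_ms: float = 150.0
    envelope_off_ms: float = 650.0
    ar_coef: float = 0.95
    noise_sd: float = 10.0
    artifact_rate: float = 0.23
    participant_jitter: float = 0.1
    n_participants: int = 25
    n_electrodes: int = 32
    n_samples: int = 250
    sampling_rate: float = 250.0
    vector_dim: int = 50
    learner_kind: str = "perfect"
    acquisition_rate: float | None = None
    exposures_to_acquire: int = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Decoding and inference settings."""

    ridge_alpha: float = 0.1
    n_perm: int = 1000
    n_boot: int = 1000
    fdr_alpha: float = 0.05
    min_exposures: int = 6
    drop_first: int = 2
    window_ms: tuple[float, float] = (0.0, 500.0)
    timecourse_window_ms: float = 50.0
    timecourse_step_ms: float = 25.0


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run description, echoed into every report."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        def build(klass, sub):
            names = {f.name for f in dataclasses.fields(klass)}
            kwargs = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in sub.items()
                if k in names
            }
            return klass(**kwargs)

        return cls(
            paradigm=build(ParadigmConfig, obj.get("paradigm", {})),
            generator=build(GeneratorConfig, obj.get("generator", {})),
            analysis=build(AnalysisConfig, obj.get("analysis", {})),
            seed=obj.get("seed", 0),
            output_dir=obj.get("output_dir", "."),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def write_epochs_h5(epochs: EpochCollection, path) -> None:
    """Write an epoch collection to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["electrodes"] = list(epochs.electrodes)
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["tmin_ms"] = float(epochs.tmin_ms)
        parts = f.create_group("participants")
        meta = epochs.meta
        for p in epochs.participants:
            gp = parts.create_group(str(int(p)))
            gsym = gp.create_group("symbols")
            pm = meta["participant"].to_numpy() == p
            for s in np.unique(meta.loc[pm, "symbol"].to_numpy()):
                mask = pm & (meta["symbol"].to_numpy() == s)
                g = gsym.create_group(str(int(s)))
                g.create_dataset("epochs", data=epochs.data[mask].astype(np.float32))
                sub = meta.loc[mask]
                g.attrs["exposure_indices"] = sub["exposure_index"].to_numpy(dtype=np.int64)
                g.attrs["n_presentations"] = int(sub["n_presentations"].iloc[0])
                g.attrs["signal_present"] = sub["signal_present"].to_numpy(dtype=bool)
                g.attrs["artifact_injected"] = sub["artifact_injected"].to_numpy(dtype=bool)


def read_epochs_h5(path) -> EpochCollection:
    """Read an epoch collection; exact round-trip of :func:`write_epochs_h5`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ValueError("not an epochs container: missing schema_version")
        if int(version) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version} (expected {SCHEMA_VERSION})")
        for attr in ("electrodes", "sfreq", "tmin_ms"):
            if attr not in f.attrs:
                raise ValueError(f"epochs container missing root attribute {attr!r}")
        electrodes = tuple(str(e) for e in f.attrs["electrodes"])
        sfreq = float(f.attrs["sfreq"])
        tmin_ms = float(f.attrs["tmin_ms"])

        blocks, rows = [], []
        for pid in sorted(f["participants"], key=int):
            gsym = f["participants"][pid].get("symbols")
            if gsym is None:
                continue  # participant with no recorded symbols (r = 0)
            for sid in sorted(gsym, key=int):
                g = gsym[sid]
                data = g["epochs"][()]
                if data.ndim != 3 or data.shape[1] != len(electrodes):
                    raise ValueError(
                        f"epochs shape {data.shape} disagrees with "
                        f"{len(electrodes)} named electrodes"
                    )
                exp = np.asarray(g.attrs["exposure_indices"], dtype=np.int64)
                if exp.size != data.shape[0]:
                    raise ValueError("exposure_indices length does not match epoch count")
                blocks.append(data)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": int(pid),
                            "symbol": int(sid),
                            "exposure_index": exp,
                            "n_presentations": int(g.attrs["n_presentations"]),
                            "signal_present": np.asarray(g.attrs["signal_present"], dtype=bool),
                            "artifact_injected": np.asarray(g.attrs["artifact_injected"], dtype=bool),
                        }
                    )
                )
        if not blocks:
            raise ValueError("epochs container holds no epochs")
        data = np.concatenate(blocks, axis=0)
        meta = pd.concat(rows, ignore_index=True)
    return EpochCollection(data=data, meta=meta, sfreq=sfreq, tmin_ms=tmin_ms, electrodes=electrodes)


def write_word_vectors(vectors: WordVectors, path) -> None:
    """Write vectors in word2vec text format (header "count dim")."""
    with open(path, "w") as fh:
        fh.write(f"{vectors.n_words} {vectors.dim}\n")
        for label, row in zip(vectors.labels, vectors.Y):
            fh.write(label + " " + " ".join(format(x, ".8g") for x in row) + "\n")


def read_word_vectors(path, lexicon: tuple[str, ...] | None = None) -> WordVectors:
    """Read word2vec text vectors; optionally align rows to a symbol lexicon.

    With a lexicon, the returned rows follow lexicon order and any lexicon
    word missing from the file is an error naming it.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("line 1: expected header 'count dim'")
        count, dim = int(header[0]), int(header[1])
        labels: list[str] = []
        rows: list[np.ndarray] = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != dim + 1:
                raise ValueError(f"line {lineno}: expected 1 label + {dim} values, got {len(parts)} fields")
            label = parts[0]
            if label in seen:
                raise ValueError(f"line {lineno}: duplicate label {label!r}")
            seen.add(label)
            try:
                rows.append(np.array([float(x) for x in parts[1:]]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric value ({exc})") from None
            labels.append(label)
    if len(labels) != count:
        raise ValueError(f"header promises {count} words but file has {len(labels)}")
    Y = np.vstack(rows)
    if lexicon is not None:
        index = {l: i for i, l in enumerate(labels)}
        missing = [w for w in lexicon if w not in index]
        if missing:
            raise ValueError(f"lexicon words absent from vector file: {missing}")
        order = [index[w] for w in lexicon]
        Y = Y[order]
        labels = list(lexicon)
    return WordVectors(Y=Y, labels=tuple(labels))
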