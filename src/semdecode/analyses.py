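"""The four decoding analyses: whole-window semantics, sliding time course,
onset of acquisition over trial triples, and the electrode-group searchlight.

Each run orchestrates trial selection, averaging, window/electrode selection,
ridge decoding with the 2 vs. 2 test, permutation inference, and BY-FDR
correction, and returns a self-describing :class:`AnalysisReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoding import PairwiseDecoder, TwoVsTwoResult
from .epochs import EpochCollection, WindowSpec
from .generate import WordVectors
from .io import AnalysisConfig
from .montage import Montage
from .preprocessing import average_selected, flatten, select_electrodes, select_trials, select_window
from .stats import bootstrap_accuracy_diff, draw_permutations, fdr_bhy, permutation_pvalue

__all__ = [
    "AnalysisReport",
    "run_semantic_analysis",
    "run_timecourse",
    "run_onset",
    "run_searchlight",
]


@dataclass
class AnalysisReport:
    """Per-unit accuracies with raw and FDR-corrected significance.

    ``table`` has one row per analysis unit (time window, electrode group,
    or trial window); ``extra`` carries analysis-specific results such as
    the bootstrap comparison of trial windows.
    """

    analysis: str
    table: pd.DataFrame
    config: dict
    seed: int
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "analysis": self.analysis,
            "seed": self.seed,
            "config": self.config,
            "rows": self.table.to_dict(orient="records"),
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=_jsonable)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _aligned_targets(vectors: WordVectors, symbols: np.ndarray) -> np.ndarray:
    return vectors.Y[np.asarray(symbols, dtype=int)]


def run_semantic_analysis(
    epochs: EpochCollection,
    vectors: WordVectors,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Whole-window decoding: can the symbol's word vector be predicted?

    Selects symbols with at least ``min_exposures`` presentations, drops the
    first ``drop_first`` exposures, averages all remaining trials across
    participants, restricts to the analysis window (default 0–500 ms, before
    the word choices appear), and runs leave-two-out 2 vs. 2 decoding with a
    permutation test.
    """
    cfg = config or AnalysisConfig()
    sel = select_trials(epochs, min_exposures=cfg.min_exposures, drop_first=cfg.drop_first)
    tensor = select_window(average_selected(sel), WindowSpec(*cfg.window_ms))
    X = flatten(tensor)
    Y = _aligned_targets(vectors, tensor.symbols)

    decoder = PairwiseDecoder(X.X, alpha=cfg.ridge_alpha)
    observed = decoder.evaluate(Y)
    perms = draw_permutations(Y.shape[0], cfg.n_perm, seed)
    perm = permutation_pvalue(decoder, Y, perms, observed=observed.accuracy, seed=seed)
    significant = fdr_bhy(np.array([perm.p_value]), alpha=cfg.fdr_alpha)[0]

    table = pd.DataFrame(
        [
            {
                "window_start_ms": cfg.window_ms[0],
                "window_end_ms": cfg.window_ms[1],
                "n_symbols": int(tensor.n_symbols),
                "n_pairs": observed.n_pairs,
                "accuracy": observed.accuracy,
                "p_value": perm.p_value,
                "significant": bool(significant),
            }
        ]
    )
    return AnalysisReport(
        analysis="semantic",
        table=table,
        config=_cfg_dict(cfg),
        seed=seed,
        extra={"permutation": perm.to_dict()},
    )


def run_timecourse(
    epochs: EpochCollection,
    vectors: WordVectors,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    window_len_ms: float | None = None,
    step_ms: float | None = None,
) -> AnalysisReport:
    """Sliding-window time course of 2 vs. 2 accuracy.

    Windows of ``window_len_ms`` (default 50 ms) slide in ``step_ms``
    (default 25 ms) steps from 0 until the last start that fits in the epoch;
    one permutation p-value per window (shared shuffles for comparability)
    and BY-FDR correction across windows.
    """
    cfg = config or AnalysisConfig()
    wlen = cfg.timecourse_window_ms if window_len_ms is None else window_len_ms
    step = cfg.timecourse_step_ms if step_ms is None else step_ms

    sel = select_trials(epochs, min_exposures=cfg.min_exposures, drop_first=cfg.drop_first)
    tensor = average_selected(sel)
    span_ms = tensor.data.shape[2] * 1000.0 / tensor.sfreq
    if wlen > span_ms:
        raise ValueError(f"window length {wlen} ms exceeds the {span_ms} ms epoch span")
    starts = np.arange(tensor.tmin_ms, tensor.tmin_ms + span_ms - wlen + 1e-9, step)

    Y = _aligned_targets(vectors, tensor.symbols)
    perms = draw_permutations(Y.shape[0], cfg.n_perm, seed)

    rows = []
    for start in starts:
        wt = select_window(tensor, WindowSpec(float(start), float(start + wlen)))
        decoder = PairwiseDecoder(flatten(wt).X, alpha=cfg.ridge_alpha)
        res = decoder.evaluate(Y)
        perm = permutation_pvalue(decoder, Y, perms, observed=res.accuracy, seed=seed)
        rows.append(
            {
                "window_start_ms": float(start),
                "window_end_ms": float(start + wlen),
                "accuracy": res.accuracy,
                "p_value": perm.p_value,
            }
        )
    table = pd.DataFrame(rows).sort_values("window_start_ms", ignore_index=True)
    table["significant"] = fdr_bhy(table["p_value"].to_numpy(), alpha=cfg.fdr_alpha)
    return AnalysisReport(
        analysis="timecourse",
        table=table,
        config={**_cfg_dict(cfg), "window_len_ms": wlen, "step_ms": step},
        seed=seed,
    )


TRIAL_WINDOWS = ((1, 3), (2, 4), (3, 5), (4, 6))
ONSET_TIME_WINDOWS = ((0.0, 500.0), (0.0, 700.0))


def run_onset(
    epochs: EpochCollection,
    vectors: WordVectors,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Onset-of-acquisition: decode averages of overlapping trial triples.

    For the trial windows (1–3), (2–4), (3–5), (4–6) — drawn from the first
    six exposures of symbols presented at least six times — and the time
    windows 0–500 and 0–700 ms, run the decoding pipeline; then bootstrap
    the accuracy difference between trial windows (4–6) and (1–3) within
    each time window (symbols resampled with replacement).
    """
    cfg = config or AnalysisConfig()
    rows = []
    results: dict[tuple, TwoVsTwoResult] = {}
    symbol_sets = {}
    for tw in TRIAL_WINDOWS:
        sel = select_trials(epochs, min_exposures=cfg.min_exposures, trial_window=tw)
        tensor_full = average_selected(sel)
        symbol_sets[tw] = tuple(tensor_full.symbols.tolist())
        Y = _aligned_targets(vectors, tensor_full.symbols)
        for win in ONSET_TIME_WINDOWS:
            tensor = select_window(tensor_full, WindowSpec(*win))
            decoder = PairwiseDecoder(flatten(tensor).X, alpha=cfg.ridge_alpha)
            res = decoder.evaluate(Y)
            perms = draw_permutations(Y.shape[0], cfg.n_perm, seed)
            perm = permutation_pvalue(decoder, Y, perms, observed=res.accuracy, seed=seed)
            results[(tw, win)] = res
            rows.append(
                {
                    "trial_window": f"{tw[0]}-{tw[1]}",
                    "window_start_ms": win[0],
                    "window_end_ms": win[1],
                    "n_symbols": int(tensor.n_symbols),
                    "accuracy": res.accuracy,
                    "p_value": perm.p_value,
                }
            )
    table = pd.DataFrame(rows)
    table["significant"] = fdr_bhy(table["p_value"].to_numpy(), alpha=cfg.fdr_alpha)

    extra = {}
    if symbol_sets[(1, 3)] == symbol_sets[(4, 6)]:
        for win in ONSET_TIME_WINDOWS:
            comp = bootstrap_accuracy_diff(
                results[((1, 3), win)], results[((4, 6), win)], n_boot=cfg.n_boot, seed=seed
            )
            extra[f"bootstrap_4-6_vs_1-3_{int(win[0])}-{int(win[1])}ms"] = comp.to_dict()
    else:  # differing survivors make the pairwise outcomes incomparable
        extra["bootstrap_skipped"] = "symbol sets differ between trial windows"
    return AnalysisReport(analysis="onset", table=table, config=_cfg_dict(cfg), seed=seed, extra=extra)


SEARCHLIGHT_WINDOWS = ((0.0, 500.0), (500.0, 1000.0), (0.0, 1000.0))


def run_searchlight(
    epochs: EpochCollection,
    vectors: WordVectors,
    montage: Montage,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Electrode-group searchlight over three time windows.

    Each group is a central electrode plus its immediate neighbors; the
    group's 2 vs. 2 accuracy is annotated to the central electrode.
    Permutation shuffles are shared across groups (comparable nulls), and
    BY-FDR is applied across groups within each time window.
    """
    cfg = config or AnalysisConfig()
    montage.validate_covers(epochs.electrodes)
    sel = select_trials(epochs, min_exposures=cfg.min_exposures, drop_first=cfg.drop_first)
    tensor = average_selected(sel)
    Y = _aligned_targets(vectors, tensor.symbols)
    perms = draw_permutations(Y.shape[0], cfg.n_perm, seed)

    rows = []
    for win in SEARCHLIGHT_WINDOWS:
        wt = select_window(tensor, WindowSpec(*win))
        pvals, accs = [], []
        for e in epochs.electrodes:
            group = [g for g in montage.group(e) if g in epochs.electrodes]
            gt = select_electrodes(wt, group)
            decoder = PairwiseDecoder(flatten(gt).X, alpha=cfg.ridge_alpha)
            res = decoder.evaluate(Y)
            perm = permutation_pvalue(decoder, Y, perms, observed=res.accuracy, seed=seed)
            accs.append(res.accuracy)
            pvals.append(perm.p_value)
        sig = fdr_bhy(np.array(pvals), alpha=cfg.fdr_alpha)
        for e, a, p, s in zip(epochs.electrodes, accs, pvals, sig):
            x, y = montage.positions[e]
            rows.append(
                {
                    "window_start_ms": win[0],
                    "window_end_ms": win[1],
                    "electrode": e,
                    "x": x,
                    "y": y,
                    "group_size": len(montage.group(e)),
                    "accuracy": a,
                    "p_value": p,
                    "significant": bool(s),
                }
            )
    table = pd.DataFrame(rows)
    return AnalysisReport(analysis="searchlight", table=table, config=_cfg_dict(cfg), seed=seed)


def _cfg_dict(cfg: AnalysisConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)
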