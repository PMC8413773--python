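"""Orchestrated analyses: whole-window decoding, time course, onset, searchlight."""

import numpy as np
import pandas as pd
import pytest

import semdecode as sd
from semdecode.io import AnalysisConfig

FAST = AnalysisConfig(n_perm=60, n_boot=100)


class TestMontage:
    def test_standard_32_is_valid(self):
        m = sd.standard_montage_32()
        assert len(m.names) == 32
        for e in m.names:
            assert len(m.neighbors[e]) >= 1
            for n in m.neighbors[e]:
                assert e in m.neighbors[n]  # symmetric

    def test_group_is_center_plus_neighbors(self):
        m = sd.standard_montage_32()
        g = m.group("Cz")
        assert g[0] == "Cz"
        assert set(g[1:]) == set(m.neighbors["Cz"])

    def test_asymmetric_neighbors_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sd.Montage(
                names=("A", "B"),
                positions={"A": (0, 0), "B": (1, 0)},
                neighbors={"A": ("B",), "B": ("A", "A")} | {"B": ()},
            )

    def test_coverage_check_names_missing(self):
        m = sd.standard_montage_32()
        with pytest.raises(ValueError, match="XX1"):
            m.validate_covers(["Cz", "XX1"])


class TestSemanticAnalysis:
    def test_deterministic_reports(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2)
        a = sd.run_semantic_analysis(ep, vec, config=FAST, seed=3)
        b = sd.run_semantic_analysis(ep, vec, config=FAST, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_gain_near_chance(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=0.0, n_participants=2)
        rep = sd.run_semantic_analysis(ep, vec, config=FAST, seed=3)
        # between-dataset spread of the 2 vs. 2 statistic is wide; the
        # permutation test, not a fixed band, carries the inference
        assert abs(rep.table["accuracy"].iloc[0] - 0.5) < 0.3
        assert not rep.table["significant"].iloc[0] or rep.table["p_value"].iloc[0] > 0.01

    def test_high_gain_significant(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=10.0, n_participants=2)
        rep = sd.run_semantic_analysis(ep, vec, config=FAST, seed=3)
        assert rep.table["accuracy"].iloc[0] > 0.9
        assert rep.table["significant"].iloc[0]


class TestTimecourse:
    def test_window_count_and_ordering(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2)
        rep = sd.run_timecourse(ep, vec, config=AnalysisConfig(n_perm=10), seed=1)
        starts = rep.table["window_start_ms"].to_numpy()
        assert len(starts) == 39
        assert starts[0] == 0.0 and starts[-1] == 950.0
        assert np.all(np.diff(starts) == 25.0)

    def test_single_window_equals_semantic_analysis(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2)
        tc = sd.run_timecourse(ep, vec, config=FAST, seed=2, window_len_ms=500.0, step_ms=1000.0)
        sem = sd.run_semantic_analysis(ep, vec, config=FAST, seed=2)
        assert len(tc.table) == 1
        assert tc.table["accuracy"].iloc[0] == pytest.approx(sem.table["accuracy"].iloc[0])
        assert tc.table["p_value"].iloc[0] == pytest.approx(sem.table["p_value"].iloc[0])

    def test_window_longer_than_epoch_errors(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2)
        with pytest.raises(ValueError):
            sd.run_timecourse(ep, vec, config=FAST, window_len_ms=2000.0)

    def test_significant_windows_confined_to_envelope_support(self, make_dataset):
        """The planted signal lives in 150-650 ms; at high gain only windows
        overlapping that support should survive FDR."""
        # n_perm must resolve p-values below the BY step-up thresholds
        # (~k * alpha / (m * c(m)) with m = 39 windows), hence 499 shuffles
        ep, vec, _ = make_dataset(seed=5, gain=10.0, n_participants=2)
        rep = sd.run_timecourse(ep, vec, config=AnalysisConfig(n_perm=499), seed=2)
        sig = rep.table[rep.table["significant"]]
        assert len(sig) > 0
        for _, row in sig.iterrows():
            assert row["window_end_ms"] > 150.0 and row["window_start_ms"] < 650.0


class TestOnset:
    def test_eight_cells_reported(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=3)
        rep = sd.run_onset(ep, vec, config=AnalysisConfig(n_perm=20, n_boot=50), seed=1)
        assert len(rep.table) == 8
        assert set(rep.table["trial_window"]) == {"1-3", "2-4", "3-5", "4-6"}

    def test_uniform_signal_gives_comparable_windows(self, make_dataset):
        # signal from exposure 2 onward (perfect learner): every trial triple
        # beyond the first carries signal, so no dramatic (4-6) vs (1-3) gap
        ep, vec, _ = make_dataset(seed=5, gain=10.0, n_participants=3)
        rep = sd.run_onset(ep, vec, config=AnalysisConfig(n_perm=20, n_boot=100), seed=1)
        accs = rep.table.set_index(["trial_window", "window_end_ms"])["accuracy"]
        # (2-4) onward all contain only acquired trials at high gain
        for tw in ("2-4", "3-5", "4-6"):
            assert accs[(tw, 700.0)] > 0.85


class TestSearchlight:
    def test_row_count_and_annotation(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2,
                                  electrodes=sd.standard_montage_32().names)
        m = sd.standard_montage_32()
        rep = sd.run_searchlight(ep, vec, m, config=AnalysisConfig(n_perm=10), seed=1)
        assert len(rep.table) == 32 * 3
        row = rep.table.iloc[0]
        assert {"electrode", "x", "y", "accuracy", "p_value", "significant"} <= set(rep.table.columns)
        assert row["group_size"] == len(m.group(row["electrode"]))

    def test_full_neighbor_montage_reproduces_global_accuracy(self, make_dataset):
        names = ("A", "B", "C", "D")
        ep, vec, _ = make_dataset(seed=5, gain=3.0, n_participants=2,
                                  n_electrodes=4, electrodes=names)
        montage = sd.Montage(
            names=names,
            positions={n: (float(i), 0.0) for i, n in enumerate(names)},
            neighbors={n: tuple(m for m in names if m != n) for n in names},
        )
        cfg = AnalysisConfig(n_perm=10)
        rep = sd.run_searchlight(ep, vec, montage, config=cfg, seed=1)
        sem = sd.run_semantic_analysis(ep, vec, config=cfg, seed=1)
        win = rep.table[(rep.table["window_start_ms"] == 0.0) & (rep.table["window_end_ms"] == 500.0)]
        # every group contains all electrodes in some order; cosine outcomes
        # are order-invariant because the feature set is identical
        for acc in win["accuracy"]:
            assert acc == pytest.approx(sem.table["accuracy"].iloc[0])

    def test_missing_electrode_errors(self, make_dataset):
        ep, vec, _ = make_dataset(seed=5, gain=1.0, n_participants=2)
        m = sd.standard_montage_32()
        with pytest.raises(ValueError):
            sd.run_searchlight(ep, vec, m, config=AnalysisConfig(n_perm=5), seed=1)
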