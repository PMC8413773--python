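"""Trimming, baseline correction, artifact rejection, trial selection,
averaging, and window/electrode selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import semdecode as sd
from semdecode.epochs import EpochCollection, SelectedTensor, WindowSpec


def make_epochs(data, sfreq=250.0, tmin_ms=0.0, meta=None, electrodes=None):
    data = np.asarray(data, dtype=np.float64)
    n, ne, _ = data.shape
    if meta is None:
        meta = pd.DataFrame(
            {
                "participant": 0,
                "symbol": np.arange(n),
                "exposure_index": 1,
                "n_presentations": 1,
                "signal_present": False,
                "artifact_injected": False,
            }
        )
    if electrodes is None:
        electrodes = tuple(f"E{i}" for i in range(ne))
    return EpochCollection(data=data, meta=meta, sfreq=sfreq, tmin_ms=tmin_ms, electrodes=electrodes)


class TestTrim:
    def test_wide_epoch_trimmed_to_one_second(self):
        # -1000..2000 ms at 250 Hz = 750 samples; [0, 1000) keeps 250
        ep = make_epochs(np.random.default_rng(0).normal(size=(2, 3, 750)), tmin_ms=-1000.0)
        out = sd.trim_epochs(ep)
        assert out.n_samples == 250
        assert out.tmin_ms == 0.0
        assert np.array_equal(out.data[0], ep.data[0, :, 250:500])

    def test_idempotent(self):
        ep = make_epochs(np.zeros((1, 2, 250)))
        out = sd.trim_epochs(ep)
        assert out is ep or np.array_equal(out.data, ep.data)

    def test_sampling_rate_sets_length(self):
        ep = make_epochs(np.zeros((1, 2, 100)), sfreq=100.0)
        assert sd.trim_epochs(ep).n_samples == 100

    def test_short_epochs_error(self):
        ep = make_epochs(np.zeros((1, 2, 200)))  # only 800 ms
        with pytest.raises(ValueError):
            sd.trim_epochs(ep)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((1, 2, 300), 7.0), tmin_ms=-200.0)
        out = sd.baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_arithmetic(self):
        data = np.zeros((1, 1, 300))
        data[0, 0, :50] = 5.0  # -200..0 ms span at 250 Hz = samples 0..49
        data[0, 0, 100] = 12.0
        ep = make_epochs(data, tmin_ms=-200.0)
        out = sd.baseline_correct(ep)
        assert out.data[0, 0, 100] == pytest.approx(7.0)

    def test_missing_baseline_span_errors(self):
        ep = make_epochs(np.zeros((1, 1, 250)), tmin_ms=0.0)
        with pytest.raises(ValueError):
            sd.baseline_correct(ep)

    def test_second_application_noop_if_span_retained(self):
        ep = make_epochs(np.random.default_rng(1).normal(size=(2, 2, 300)), tmin_ms=-200.0)
        once = sd.baseline_correct(ep)
        twice = sd.baseline_correct(once)
        assert np.allclose(once.data, twice.data)


def rejection_fixture_set():
    """Constructed epochs at the rejection boundaries (250 Hz).

    Returns (epochs, expected_rejected_mask)."""
    n_samp = 250
    epochs = np.zeros((5, 2, n_samp))
    # 0: one electrode ranging -51..+50 μV -> 101 μV p2p, rejected
    epochs[0, 0, 10] = -51.0
    epochs[0, 0, 30] = 50.0
    # 1: exactly 100 μV p2p, smooth ramp (0.8 μV/step), retained
    epochs[1, 1] = np.linspace(0.0, 100.0, n_samp)
    # 2: adjacent-sample jump of 41 μV = 10.25 μV/ms, rejected
    epochs[2, 0, 100] = 41.0
    epochs[2, 0, 101:] = 41.0
    # 3: jump of 39 μV = 9.75 μV/ms, retained
    epochs[3, 1, 100] = 39.0
    epochs[3, 1, 101:] = 39.0
    # 4: all zeros, retained
    expected_rejected = np.array([True, False, True, False, False])
    return make_epochs(epochs), expected_rejected


class TestRejection:
    def test_boundary_fixtures_exact(self):
        ep, expected = rejection_fixture_set()
        kept, report = sd.reject_artifacts(ep)
        assert report.n_rejected == int(expected.sum())
        assert kept.n_epochs == int((~expected).sum())
        assert set(kept.meta["symbol"]) == set(np.nonzero(~expected)[0])
        assert report.n_p2p == 1 and report.n_gradient >= 1

    def test_invariant_to_electrode_order_and_zero_channel(self):
        ep, expected = rejection_fixture_set()
        _, r1 = sd.reject_artifacts(ep)
        flipped = make_epochs(ep.data[:, ::-1, :])
        _, r2 = sd.reject_artifacts(flipped)
        padded = make_epochs(np.concatenate([ep.data, np.zeros((5, 1, 250))], axis=1))
        _, r3 = sd.reject_artifacts(padded)
        assert r1.n_rejected == r2.n_rejected == r3.n_rejected

    def test_rejection_matches_injected_ground_truth(self, make_dataset):
        ep, _, _ = make_dataset(seed=17, gain=1.0, n_participants=2, artifact_rate=0.2)
        kept, report = sd.reject_artifacts(ep)
        assert report.n_rejected == int(ep.meta["artifact_injected"].sum())
        assert not kept.meta["artifact_injected"].any()


class TestSelectTrials:
    def _collection(self, exposures_by_symbol):
        rows, data = [], []
        for s, n in exposures_by_symbol.items():
            for e in range(1, n + 1):
                rows.append((0, s, e, n))
                data.append(np.full((2, 10), float(s * 100 + e)))
        meta = pd.DataFrame(rows, columns=["participant", "symbol", "exposure_index", "n_presentations"])
        meta["signal_present"] = False
        meta["artifact_injected"] = False
        return make_epochs(np.stack(data), meta=meta)

    def test_underexposed_symbol_contributes_nothing(self):
        ep = self._collection({0: 5, 1: 8})
        out = sd.select_trials(ep, min_exposures=6, drop_first=2)
        assert set(out.meta["symbol"]) == {1}
        assert out.meta.attrs["symbols_removed"] == [0]

    def test_drop_first_keeps_remainder(self):
        ep = self._collection({0: 6})
        out = sd.select_trials(ep, min_exposures=6, drop_first=2)
        assert sorted(out.meta["exposure_index"]) == [3, 4, 5, 6]

    def test_trial_window_exact(self):
        ep = self._collection({0: 8})
        out = sd.select_trials(ep, min_exposures=6, trial_window=(4, 6))
        assert sorted(out.meta["exposure_index"]) == [4, 5, 6]

    def test_all_excluded_errors(self):
        ep = self._collection({0: 3})
        with pytest.raises(ValueError):
            sd.select_trials(ep, min_exposures=6)


class TestAverage:
    def test_mean_of_one_is_identity(self):
        ep = make_epochs(np.random.default_rng(3).normal(size=(4, 3, 20)))
        t = sd.average_selected(ep)
        assert np.allclose(t.data, ep.data)

    def test_symmetric_trials_cancel(self):
        x = np.random.default_rng(4).normal(size=(1, 2, 10))
        data = np.concatenate([x, -x])
        meta = pd.DataFrame(
            {"participant": [0, 1], "symbol": 0, "exposure_index": [1, 1],
             "n_presentations": 1, "signal_present": False, "artifact_injected": False}
        )
        t = sd.average_selected(make_epochs(data, meta=meta))
        assert np.allclose(t.data, 0.0)

    def test_pooled_mean_matches_brute_force(self, rng):
        n = 30
        meta = pd.DataFrame(
            {"participant": rng.integers(0, 3, n), "symbol": rng.integers(0, 4, n),
             "exposure_index": 1, "n_presentations": 1,
             "signal_present": False, "artifact_injected": False}
        )
        data = rng.normal(size=(n, 2, 5))
        t = sd.average_selected(make_epochs(data, meta=meta))
        for i, s in enumerate(t.symbols):
            mask = meta["symbol"].to_numpy() == s
            assert np.allclose(t.data[i], data[mask].sum(axis=0) / mask.sum())

    def test_participant_relabeling_invariance(self, rng):
        data = rng.normal(size=(10, 2, 5))
        meta = pd.DataFrame(
            {"participant": rng.integers(0, 2, 10), "symbol": rng.integers(0, 3, 10),
             "exposure_index": 1, "n_presentations": 1,
             "signal_present": False, "artifact_injected": False}
        )
        meta2 = meta.copy()
        meta2["participant"] = 5 - meta["participant"]
        a = sd.average_selected(make_epochs(data, meta=meta))
        b = sd.average_selected(make_epochs(data, meta=meta2))
        assert np.allclose(a.data, b.data)


class TestWindowAndFlatten:
    def _tensor(self, ns=3, ne=4, l=250):
        data = np.arange(ns * ne * l, dtype=float).reshape(ns, ne, l)
        return SelectedTensor(
            data=data, symbols=np.arange(ns),
            electrodes=tuple(f"E{i}" for i in range(ne)), sfreq=250.0, tmin_ms=0.0,
        )

    @pytest.mark.parametrize(
        "start,end,expected",
        [(0, 500, list(range(0, 125))), (25, 75, list(range(7, 19)))],
    )
    def test_sample_index_convention(self, start, end, expected):
        idx = WindowSpec(start, end).sample_indices(250.0, 250)
        assert idx.tolist() == expected

    @settings(max_examples=50, deadline=None)
    @given(
        start=st.integers(0, 900),
        length=st.integers(10, 100),
        fs=st.sampled_from([100.0, 250.0, 500.0]),
    )
    def test_sample_indices_match_enumeration(self, start, length, fs):
        spec = WindowSpec(float(start), float(start + length))
        brute = [k for k in range(int(fs)) if start <= k * 1000.0 / fs < start + length]
        if brute:
            assert spec.sample_indices(fs, int(fs)).tolist() == brute
        else:
            with pytest.raises(ValueError):
                spec.sample_indices(fs, int(fs))

    def test_flatten_column_count_and_order(self):
        t = self._tensor()
        X = sd.flatten(t)
        assert X.X.shape == (3, 1000)
        # electrode-major, time-minor: column e*l + k holds (e, k)
        assert np.array_equal(X.X[1].reshape(4, 250), t.data[1])

    def test_full_window_then_flatten_is_identity(self):
        t = self._tensor()
        a = sd.flatten(sd.select_window(t, WindowSpec(0, 1000)))
        b = sd.flatten(t)
        assert np.array_equal(a.X, b.X)

    def test_electrode_selection(self):
        t = self._tensor()
        g = sd.select_electrodes(t, ["E2", "E0"])
        assert g.electrodes == ("E2", "E0")
        assert np.array_equal(g.data[:, 0], t.data[:, 2])
        with pytest.raises(ValueError, match="E9"):
            sd.select_electrodes(t, ["E9"])
        with pytest.raises(ValueError):
            sd.select_electrodes(t, [])

    def test_window_32_electrodes_250_samples_gives_8000_columns(self):
        t = self._tensor(ne=32)
        assert sd.flatten(t).X.shape[1] == 8000
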