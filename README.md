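# semdecode

Semantic decoding of EEG recorded while people learn an artificial language.

`semdecode` simulates a symbol-learning experiment — participants repeatedly
see unfamiliar symbols, guess which of four words each symbol means, and get
feedback — together with the multichannel EEG evoked by each symbol
presentation. It then decodes the *meaning* of each symbol from the EEG:
ridge regression maps averaged evoked responses to distributional word
vectors, and the mapping is scored with the leave-two-out **2 vs. 2 test**,
where chance is 50%. Statistical machinery (permutation tests,
Benjamini–Yekutieli FDR, symbol-level bootstrap) and four ready-made analyses
(whole-window decoding, decoding time course, onset of acquisition, and an
electrode searchlight) come included.

Because real recordings of this kind are rarely shareable, the package ships
a forward-model generator with known ground truth: you choose where the
semantic signal lives in time (envelope), on the scalp (mixing/electrode
subset), and from which exposure it appears (learner model), then check that
the pipeline recovers exactly that.

## Quick start

```python
import semdecode as sd

# simulate 4 participants with a planted semantic signal and 23% artifacts
fwd = sd.ForwardModel(gain=3.0, artifact_rate=0.23)
epochs, vectors, trials = sd.simulate_dataset(seed=7, fwd=fwd, n_participants=4)

# preprocess: trim to 0-1000 ms, reject by amplitude/gradient thresholds
epochs = sd.trim_epochs(epochs)
epochs, report = sd.reject_artifacts(epochs)

# average each well-learned symbol's later exposures, 0-500 ms window
selected = sd.select_trials(epochs, min_exposures=6, drop_first=2)
tensor = sd.select_window(sd.average_selected(selected), sd.WindowSpec(0.0, 500.0))
X, Y = sd.flatten(tensor).X, vectors.Y[tensor.symbols]

# decode and test
result = sd.evaluate_loto(X, Y, alpha=0.1)
perm = sd.permutation_test(X, Y, alpha=0.1, n_perm=500, seed=7)
print(result.accuracy, perm.p_value)
```

Running `python examples/01_simulate_and_decode.py` (the same pipeline)
prints:

```
simulated 807 epochs, 60 symbols, 50-dim word vectors
rejected 182/807 epochs (22.6%)
design matrix: 26 symbols x 4000 features (electrodes x samples in 0-500 ms)
2 vs. 2 accuracy: 76.0% over 325 pairs
permutation p-value (500 shuffles): 0.0140
null accuracies: mean 49.9%, max 80.9%
```

The other examples tell one story each:

- `examples/02_timecourse.py` — sliding 50 ms windows recover the planted
  150–650 ms signal envelope, with BY-FDR over the 39 windows.
- `examples/03_onset_of_acquisition.py` — a learner who acquires meanings
  after 3 exposures shows chance decoding over trials 1–3 and near-perfect
  decoding over trials 4–6, with a bootstrap test of the difference.
- `examples/04_searchlight.py` — signal mixed into a left-hemisphere
  electrode cluster lights up only that cluster and its montage neighbors.

## Command line

Every stage is also available as a thin CLI over the library:

```bash
semdecode simulate   --seed 7 --out runs/sim
semdecode preprocess --epochs runs/sim/epochs.h5 --out runs/pre
semdecode decode     --epochs runs/pre/epochs_clean.h5 \
                     --vectors runs/sim/vectors.vec --out runs/dec
semdecode timecourse ... ; semdecode onset ... ; semdecode searchlight ...
semdecode report     --report runs/dec/semantic.json
```

Each run writes its outputs plus `config.json` and `log.json` (seed, counts,
timing) for reproducibility. Datasets are stored as HDF5
(`/participants/<id>/symbols/<id>/epochs`, float32 µV, with exposure and
ground-truth attributes); word vectors use the plain word2vec text format.

## Package layout

| module | contents |
| --- | --- |
| `semdecode.paradigm` | block schedule, learner models, behavior simulation, closed-form baseline |
| `semdecode.generate` | word vectors, AR(1) + forward-model EEG generator, full-dataset simulation |
| `semdecode.preprocessing` | trim, baseline, artifact rejection, trial selection, averaging, windows |
| `semdecode.decoding` | ridge (primal/dual), 2 vs. 2 test, Gram-cached leave-two-out evaluator |
| `semdecode.stats` | permutation test, BY-FDR, symbol bootstrap |
| `semdecode.analyses` | semantic / timecourse / onset / searchlight analyses and reports |
| `semdecode.montage` | 32-channel 10–20 montage with neighbor structure |
| `semdecode.io` | HDF5 epochs, word2vec text vectors, run configs, montage JSON |
| `semdecode.cli` | `semdecode` command-line entry point |
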