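# Methods

This document defines the generative model, the estimators, and the
numerical and statistical choices made in `semdecode`, in enough detail to
re-derive every number the package produces.

## 1. Learning paradigm

Participants learn mappings from unfamiliar symbols to words of their native
language over feedback trials.

- **Schedule** (`build_schedule`): 19 blocks over 60 symbols. Block 1
  introduces 6 new symbols; each later block introduces 3 new symbols and
  carries over 3 symbols drawn uniformly from those already introduced, so
  every block presents 6 symbols. Presentation order within a pass over the
  block is shuffled per pass.
- **Trial**: one symbol is shown with 4 answer choices — its word plus 3
  distractors drawn without replacement from the words of the 5 other
  symbols in the block.
- **Block end** (mastery): a block ends when the participant is correct on
  ≥ 90% of the last 10 trials, or at a hard cap of 300 trials (trials beyond
  the cap are flagged `block_truncated`). Symbols are capped at 20 exposures
  within a block.
- **Learner models** (`LearnerModel`): `perfect` (knows a symbol after
  `exposures_to_acquire` exposures, default 1; eliminates known words among
  the choices and guesses uniformly over the rest), `exposure_rate`
  (acquisition probability grows per exposure), `random`.

### Closed-form baseline

For an idealized perfect learner, the expected first-exposure response
accuracy is enumerable: at a first encounter, if `k` of the 3 distractors
are words of still-unknown symbols, the learner guesses among `1 + k`
options, so accuracy is `E[1/(1+k)]` with `k ~ Hypergeometric(unknown
others, 5, 3)`. First-block encounter positions have 5,4,3,2,1,0 unknown
others; later-block new symbols have 2,1,0 (carried symbols are already
known). Averaging equally over all 60 symbols:

```
(3.125 + 18 × 2.2) / 60 = 42725/60000 ≈ 0.7121  →  71%
```

`perfect_learner_first_trial_accuracy` computes this with exact rational
arithmetic. Note that a **full simulation** of the default paradigm does
*not* converge to this number (measured ≈ 0.64): the adaptive mastery rule
ends blocks early and censors late first encounters, violating the
idealization's uniform-rank assumption. The closed form is the property of
the idealized process, and is verified against a Monte-Carlo oracle that
simulates exactly that process (hypergeometric distractor draw + uniform
guess, ≥ 10^6 trials).

## 2. Synthetic EEG generator

One epoch per trial, `n_electrodes × n_samples` at 250 Hz, in µV
(`float32` on disk).

- **Noise**: independent per-electrode AR(1), coefficient 0.95, stationary
  SD 10 µV (innovations scaled by √(1−0.95²)), filtered with
  `scipy.signal.lfilter`.
- **Signal**: on trials where the learner has acquired the symbol, the
  pattern `gain · M · y_s` is added, modulated by a Hann envelope supported
  on 150–650 ms (peak normalized to 1). `M` is a fixed
  `n_electrodes × v` mixing matrix (default N(0, 1/v) entries) shared by all
  participants, with per-participant multiplicative jitter (SD 0.1).
  `electrode_subset` zeroes all mixing rows outside the subset, confining
  the signal spatially; because the jitter is multiplicative, zero rows stay
  zero.
- **Artifacts**: with probability `artifact_rate` per epoch (default 0.23
  in the CLI generator config, 0 in the bare `ForwardModel`), a 500 µV
  spike is added at one random electrode/sample. Ground truth
  (`signal_present`, `artifact_injected`) is stored in the epoch metadata.
- **Word vectors**: `generate_word_vectors` draws standard-normal rows
  (default v = 50), unique labels, no zero rows; real vectors in word2vec
  text format can be loaded instead.
- **Determinism**: `simulate_dataset(seed=…)` derives per-participant
  schedule/behavior seeds and the vector/EEG seeds from a single root seed
  (all below 2³¹) and regenerates byte-identically.

## 3. Preprocessing

- **Trim** to [0, 1000) ms (exactly `sfreq` samples); **baseline** subtracts
  the per-channel mean over [−200, 0) ms when a pre-stimulus span exists
  (the generator's default epochs start at 0 ms and are baseline-free by
  construction).
- **Artifact rejection**: an epoch is rejected if any electrode's
  peak-to-peak amplitude exceeds 100 µV, or any adjacent-sample difference
  exceeds 10 µV/ms × (1000/fs) (= 40 µV per step at 250 Hz). Boundary cases
  (101 vs 100 µV, 41 vs 39 µV jumps) are pinned by fixture tests.
- **Trial selection**: keep symbols presented ≥ `min_exposures` times per
  participant (counted *before* rejection, stored as `n_presentations`),
  drop each symbol's first `drop_first` exposures — defaults 6 and 2 — or
  select an explicit `trial_window` of exposure indices. **Averaging** is
  the pooled (trial-weighted) mean per symbol across participants.
- **Windows**: `WindowSpec(start, end)` is half-open in ms — sample `k` is
  included iff `start ≤ tmin + k·1000/fs < end`. Flattening is
  electrode-major, time-minor.

## 4. Decoding

- **Ridge** (`fit_ridge`): per-dimension closed form with training-mean
  centering and no penalized intercept: primal
  `(XᵀX + αI)⁻¹ Xᵀ Y` when features ≤ samples, dual
  `Xᵀ (XXᵀ + αI)⁻¹ Y` otherwise (identical results; verified to 1e-10).
  Default α = 0.1.
- **2 vs. 2 test** (`two_vs_two_pair`): for a held-out pair (i, j) the test
  passes iff `d(y_i, ŷ_i) + d(y_j, ŷ_j) < d(y_i, ŷ_j) + d(y_j, ŷ_i)` with
  cosine distance; exact ties score 0.5; zero-norm vectors get distance 1
  with a warning. Chance = 50%.
- **Leave-two-out evaluator** (`evaluate_loto`/`PairwiseDecoder`): all
  `C(ns, 2)` pairs. Refitting ridge for every pair is avoided by caching:
  with training-mean centering, each held-out prediction is *linear in the
  training targets*, `ŷ_t = g_tᵀ Y_S`, where `g_t` depends only on the
  (double-centered) Gram matrix of X. All `g_t` are assembled once into a
  `2·n_pairs × ns` operator `G`, so evaluating a permutation of Y is a
  single matrix product. Cached outcomes equal naive refitting to ≤ 1e-10
  (oracle test), and permutations run in batches via `tensordot`.

## 5. Statistics

- **Permutation test**: the null shuffles the symbol→vector assignment
  (rows of Y); p = (1 + #{null ≥ observed}) / (1 + n_perm), never zero.
  Default 1000 shuffles; analyses share one shuffle set across windows or
  electrode groups so nulls are comparable.
- **BY-FDR** (`fdr_bhy`): Benjamini–Yekutieli step-up with the harmonic
  correction c(m), valid under arbitrary dependence (implemented via
  statsmodels, verified against brute-force enumeration).
- **Bootstrap** (`bootstrap_accuracy_diff`): symbols are the resampling
  unit. Each replicate redraws symbols with replacement and recomputes both
  conditions' accuracies from their cached pair-outcome matrices over pairs
  of distinct resampled symbols (replicates with < 3 distinct symbols are
  redrawn). The CI and two-sided p-value are normal-theory using the
  bootstrap SD.

A note on calibration: 2 vs. 2 pair outcomes within one dataset/shuffle
share training rows and averaged responses, so they are strongly
*positively correlated*. The SD of null accuracy across shuffles is ≈ 0.07–0.09
(ns ≈ 30–60), far larger than the `1/√(n_pairs)` binomial value. Calibration
checks therefore use the empirical between-shuffle SE; treating pairs as
independent Bernoulli trials would be wrong by an order of magnitude.

## 6. Analyses

- **Semantic** (`run_semantic_analysis`): selection (6/2), 0–500 ms window,
  LOTO 2 vs. 2, permutation p.
- **Timecourse** (`run_timecourse`): 50 ms windows, 25 ms steps (39 windows
  over a 1 s epoch), shared shuffles, BY-FDR across windows.
- **Onset** (`run_onset`): decodes exposure triples (1–3), (2–4), (3–5),
  (4–6) in 0–500 and 0–700 ms windows, and bootstraps the (4–6) − (1–3)
  difference per time window.
- **Searchlight** (`run_searchlight`): each electrode plus its montage
  neighbors, windows 0–500 / 500–1000 / 0–1000 ms, shared shuffles, BY-FDR
  across electrodes within each window. The built-in montage is a 32-channel
  10–20 layout with distance-based adjacency.

## 7. Problem sizes and verification choices

Test and example problem sizes are package choices made for runtime, not
external constraints: verification datasets use 2–8 participants, a planted
gain of 10 for recovery checks (measured whole-window accuracy rises from
≈ 0.5 at gain 0 through ≈ 0.9 at gain 3 to > 0.99 at gain 10 on
multi-participant data), and permutation counts of 199–499 where the
inference only needs that resolution. The localization test confines mixing
to an 8-electrode cluster with 10-dimensional vectors: an n-electrode subset
can only expose a rank-n projection of the target space, so small clusters
with high-dimensional vectors cap group accuracy regardless of gain.

## 8. What the generator does and does not emulate

It emulates: trial-locked evoked structure with realistic 1/f-like AR
coloring, acquisition-gated signal, participant variability, spatial
confinement, and amplitude artifacts — everything the pipeline's claims are
tested against. It does **not** emulate volume conduction from cortical
sources, eye/muscle artifact morphology, inter-electrode noise correlation,
oscillatory dynamics, or behavioral response-time structure. Conclusions
from this package are about the *pipeline* (calibration, recovery,
localization), not about brains.
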