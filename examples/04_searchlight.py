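"""Where on the scalp does the semantic signal live?

Story: the forward model confines the signal mixing to a left-hemisphere
electrode cluster.  An electrode-group searchlight (each electrode plus its
montage neighbors) should light up only over and around that cluster.
"""

import semdecode as sd
from semdecode.io import AnalysisConfig

SEED = 5

montage = sd.standard_montage_32()
cluster = ("F3", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3")
subset = tuple(montage.names.index(n) for n in cluster)

fwd = sd.ForwardModel(gain=10.0, electrode_subset=subset)
epochs, vectors, _ = sd.simulate_dataset(
    seed=SEED, fwd=fwd, n_participants=5, electrodes=montage.names, vector_dim=10
)

report = sd.run_searchlight(
    epochs, vectors, montage,
    config=AnalysisConfig(n_perm=499, min_exposures=3, drop_first=1),
    seed=SEED,
)

window = report.table[
    (report.table["window_start_ms"] == 0.0) & (report.table["window_end_ms"] == 500.0)
]
print("electrode  accuracy   p-value   significant  in-cluster")
for _, row in window.sort_values("p_value").iterrows():
    star = "*" if row["significant"] else " "
    inc = "yes" if row["electrode"] in cluster else ""
    print(f"{row['electrode']:>9}  {100 * row['accuracy']:7.1f}%   "
          f"{row['p_value']:.4f}      {star}        {inc}")

sig = window[window["significant"]]["electrode"].tolist()
print(f"\nsignificant centers (0-500 ms): {sig}")
print(f"planted cluster:                {list(cluster)}")
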