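"""Cross-validated sweep of the time-steps hyperparameter (desk scale).

Runs k-fold cross-validation at TS=1 and TS=2 on the same noisy synthetic
recording, including the plain network of matched weights-only complexity, so
the benefit of temporal-context concatenation can be separated from capacity.
Larger studies use dtcn.paired_ts_study over many seeds.
"""

from dtcn import NetConfig, SynthSpec, TrainConfig, WindowSpec, generate, ts_sweep
from dtcn.rbm import PretrainConfig

record = generate(SynthSpec(n_channels=6, n_samples=8000, mean_dwell=200.0, snr=1.0, seed=0))
base = NetConfig(window=WindowSpec(16, 8), hidden=(8, 8, 8), batch_size=18)
table, _ = ts_sweep(
    record, base, ts_values=[1, 2],
    train_config=TrainConfig(learning_rate=0.2, epochs=40, momentum=0.5),
    k=5, seed=0, pretrain_config=PretrainConfig(epochs=3, learning_rate=0.05),
)
print(table.to_string(index=False))
print("\nmean_accuracy is the k-fold mean (%); param_count counts weights only.")
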