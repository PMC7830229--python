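"""Pretrain and fine-tune one temporal-context network on synthetic data.

Generates a noisy two-state regime-switching recording, prepares overlapping
mini-batches, pretrains the connection stack with CD-1, fine-tunes with
backpropagation + gradient routing, and reports held-out accuracy.
"""

from dtcn import (
    NetworkParams,
    PretrainConfig,
    SynthSpec,
    TrainConfig,
    WindowSpec,
    evaluate,
    generate,
    make_minibatches,
    pretrain_stack,
    shuffle_minibatches,
    sliding_window,
    standardize_fold,
    train_network,
)

record = generate(SynthSpec(n_channels=6, n_samples=8000, mean_dwell=200.0, snr=1.0, seed=0))
vectors = sliding_window(record, WindowSpec(16, 8))
batches = make_minibatches(vectors, B=18)
n_train = int(len(batches) * 0.8)
train, test = standardize_fold(batches[:n_train], batches[n_train:])
train = shuffle_minibatches(train, seed=0)

params = NetworkParams.initialize((96, 8, 8, 8, 2), ts=2, seed=0)
pretrain_stack(params, train, PretrainConfig(epochs=3, learning_rate=0.05, seed=0))
params, losses = train_network(
    params, train, TrainConfig(learning_rate=0.2, epochs=40, momentum=0.5, seed=0)
)
print(f"epoch-mean cross-entropy: first {losses[0]:.3f} -> last {losses[-1]:.3f}")
print(f"held-out accuracy over surviving rows: {evaluate(params, test):.2f}%")
print("(accuracy is measured against labels voted from the pooled counts of the "
      "final classifier)")
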