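"""Two-stage windowing: series -> data vectors -> overlapping mini-batches.

A first sliding window turns the labelled series into flattened data vectors
(with per-class label counts); a second sliding window over those vectors
builds overlapping mini-batches whose instances stay in natural time order.
"""

from dtcn import SynthSpec, WindowSpec, compute_overlap, generate, make_minibatches, sliding_window

record = generate(SynthSpec(n_channels=6, n_samples=2000, seed=0))
spec = WindowSpec(w=16, s=8)

print(f"window w={spec.w}, stride s={spec.s} -> overlap {compute_overlap(spec):.0f}%")
vectors = sliding_window(record, spec)
print(f"{record.n_samples} samples x {record.n_channels} channels "
      f"-> {len(vectors)} data vectors of length {vectors[0].features.size}")
print(f"label counts of the first vector: {vectors[0].label_counts} (sum = w)")

batches = make_minibatches(vectors, B=18)  # default stride B//2: 50% overlap
print(f"second stage: {len(batches)} mini-batches of {batches[0].size} vectors;")
print(f"first batch covers start samples {batches[0].t_indices[0]}..{batches[0].t_indices[-1]}"
      f" in natural time order (step {spec.s})")
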