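"""Weights-only complexity of the network, and the matched plain network.

The concatenation sublayers multiply each later connection's fan-in by TS, so
a TS>1 network has more weights than its TS=1 counterpart with the same
hidden widths.  For a fair comparison the plain network's first hidden layers
are widened until its weights-only parameter count is closest to the
temporal-context network's.
"""

from dtcn import equivalent_dbn_config, param_count

base = (224, 20, 20, 20, 2)  # 14 channels x window 16 -> 224 inputs, 2 classes
for ts in (1, 2, 5):
    print(f"TS={ts}: network {base} has {param_count(base, ts)} weights")
for ts in (2, 5):
    widths = equivalent_dbn_config(base, ts)
    sizes = (base[0], *widths, base[-1])
    print(f"plain network matched to TS={ts}: hidden widths {widths} "
          f"-> {param_count(sizes, 1)} weights")
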