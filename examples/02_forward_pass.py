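"""Build the default CNN, run one forward pass, and count its parameters.

The default architecture mirrors the reference design for 210x210x3
histopathology inputs: eight 3x3 conv layers (8,8,16,16,24,24,32,32
filters), a 2x2 average pool after every second conv, one hidden layer
of width 100, and a 2-way output.
"""

import numpy as np

from gacnn import build_network, count_weights, flatten_weights, forward, init_weights

spec = build_network()
print("layer chain (shape after each layer):")
for layer in spec.layers:
    print("  ", layer)
print(f"flatten size: {spec.flatten_size}")
print(f"trainable parameters: {count_weights(spec):,}")

weights = init_weights(spec, dist="uniform", seed=0)
image = np.random.default_rng(0).uniform(size=spec.input_shape)
scores = forward(spec, weights, image)
print(f"class scores for a random image: benign {scores[0]:.4f}, "
      f"malignant {scores[1]:.4f} (sum {scores.sum():.4f})")

chromosome = flatten_weights(weights)
print(f"chromosome length (the GA's search space): {chromosome.size:,}")
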