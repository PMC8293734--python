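"""Evolve the CNN's weights with the genetic algorithm.

The chromosome is the flattened weight vector; fitness is the
classification error rate on the current evaluation batch.  The GA keeps
the best 8 of 20 members each generation (elitism), refills the rest by
single-point crossover and single-gene mutation, and reports the
best-ever member.  Expect a few minutes of runtime; success is more
seed-dependent than for Adam.
"""

from gacnn import (
    GAConfig, build_network, evaluate, generate_synthetic_dataset, predict,
    restore_weights, split_patientwise, train_ga,
)

ds = generate_synthetic_dataset(n_per_class=100, image_size=32, n_patients=8, seed=0)
train, test = split_patientwise(ds, train_fraction=0.7, seed=0)
spec = build_network((32, 32, 3), [4, 4], hidden_width=0)

cfg = GAConfig(population_size=20, num_parents=8, generations=200,
               batch_size=128, seed=0)
result = train_ga(spec, train, cfg)

hist = result.best_fitness_history
print(f"best batch error rate: gen 0 {hist[0]:.3f} -> final {min(hist):.3f} "
      f"(best-ever member kept)")

weights = restore_weights(result.best_weights, spec)
m = evaluate(test.labels_array(), predict(spec, weights, test.pixels_array()))
print(f"held-out patients: accuracy {m['accuracy']:.3f}, "
      f"recall {m['recall']:.3f}, precision {m['precision']:.3f}")
# The GA needs no gradients: it only ever calls the forward pass.
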