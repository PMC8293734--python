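# Methods

## Problem and model

The task is binary classification of H&E-stained breast-biopsy images
into benign and malignant cases. The classifier is a deliberately plain
CNN: a chain of valid (no padding, stride 1) 3×3 convolutions, each
followed by ReLU; a 2×2 stride-2 average pool after every second
convolution; flattening; an optional fully connected hidden layer with
ReLU; and a 2-unit output layer. Class scores are the softmax of the
output logits by default (a per-logit sigmoid mode, renormalized to sum
to one, is available for ablation). Prediction is the argmax, with ties
resolved to benign — the conservative direction is deliberate only in
the sense of determinism; recall/precision reporting makes the
false-negative cost visible.

The default architecture (210×210×3 input; 8, 8, 16, 16, 24, 24, 32, 32
filters; hidden width 100) resolves to a 9×9×32 final map, flatten size
2,592, and 288,678 trainable parameters with biases. Construction fails
eagerly if any intermediate spatial dimension would reach zero, so
invalid input-size/architecture combinations cannot train.

Conventions fixed where a plain-language description is ambiguous:

- **Pooling placement.** One 2×2 average pool after every second conv
  layer (`pool_every`, configurable). Pooling after *every* conv layer
  would make an eight-conv chain on 210×210 inputs impossible
  (the map would shrink below the kernel before layer 8).
- **Filter depth.** Filters span all input channels (F×3×3×C), the
  standard convention.
- **Odd pooling dimensions.** Floor division; the trailing row/column
  is dropped and receives no gradient.
- **Weight counting.** The conv filters alone of the default
  architecture exceed 29k parameters, so any smaller published total
  for a comparable design must rest on different (2-D filter)
  conventions; this package counts every scalar in the tensors it
  actually uses.

## Chromosome codec

All parameters serialize to one flat vector in a frozen order: conv
layers in network order (filter tensor row-major, then bias), then dense
layers (weight matrix row-major, then bias). `flatten_weights` /
`restore_weights` are exact inverses (bitwise), so the GA, the gradient
trainers, and the checkpoint format all share one parameterization.

## Trainers

**Mini-batch gradient descent** and **Adam** minimize the mean softmax
cross-entropy. The raw error rate is not differentiable, so a surrogate
loss is required for gradient training; cross-entropy is the standard
choice and its gradient at the logits is simply `softmax − onehot`. The
backward pass is hand-written reverse-mode differentiation through
dense, ReLU, flatten, average-pool (gradient spread uniformly over each
2×2 block), and convolution (filter gradient by correlating inputs with
upstream gradients; input gradient by full correlation with spatially
flipped filters). It is verified against central finite differences
(step 1e−5, max relative error ≤ 1e−4 over ≥ 100 probed parameters).
Defaults: α = 0.001; Adam β₁ = 0.9, β₂ = 0.999, ε = 1e−8 (the standard
constants of the original method). One iteration = one mini-batch
update; batches cycle through the training set in seeded shuffled order,
reshuffled each epoch.

**Genetic algorithm.** Fitness = error rate (FP+FN)/N on the evaluation
batch, evaluated for every member each generation either on the next
mini-batch (`minibatch`, default) or on the whole training set
(`fullbatch`). Selection keeps the `num_parents` lowest-error members
(stable sort, ties to lower index) unchanged — elitism, which makes the
per-generation best error non-increasing under full-batch fitness.
Offspring are produced by single-point crossover of cyclically paired
parents (cut drawn uniformly from [1, L−1] per pair; one offspring kept
per pair by default), then mutation. Mutation semantics: with
probability `mutation_rate` (default 0.1) exactly one uniformly chosen
gene receives a uniform(−1, 1) increment; a per-gene mode exists for
ablation. Because mini-batch fitness is noisy, the reported solution is
the best-*ever* member by recorded fitness, not the final-generation
best. Defaults: population 40, 8 parents (≈20 % of the population —
the fraction of members that typically carries useful fitness), mutation
rate 0.1, uniform initialization.

**Initialization** (both trainers): i.i.d. uniform(−0.1, 0.1) or
N(0, 0.1²), configurable; every population member gets an independent
seeded stream spawned from the master seed, so runs are exactly
reproducible.

## Data handling

Filenames follow the `BIOPSY_CLASS_SUBTYPE-YEAR-SLIDE-MAG-SEQ.EXT`
grammar; the patient is `YEAR-SLIDE`, labeling ignores subtype and
magnification (both kept as metadata). Images are decoded as RGB,
bilinearly resized, and scaled to [0, 1] by division by 255. No stain
normalization or augmentation is applied.

**Patient-wise split.** Because one biopsy yields many images, a random
image-level split would leak patient texture into the test set. Patients
are shuffled by seed and assigned greedily to the training side until
its image count first reaches the target fraction (default 0.7); an
exact image-level 70/30 is generally impossible patient-wise, so the
realized train fraction is ≥ the requested one. With few patients the
test side can be class-imbalanced; metrics with empty denominators are
reported as n/a rather than 0.

## Synthetic fixture

The generator emulates the coarse visual contrast of the two classes:
benign images have a few (Poisson, mean 6) large pale blobs on a pink
background; malignant images many (mean 25, with extra variance from a
gamma-distributed rate) small dark-purple blobs on a slightly darker
background, mimicking dense hyperchromatic nuclei. Gaussian pixel noise
(sd 0.03) is added and images are quantized to 8 bits so a PNG
write/read round trip is bitwise exact. The default of 8 patients at the
200-image scale (25 images per patient) mirrors the many-images-per-
patient structure of real biopsy datasets, which is what makes
patient-wise splitting a meaningful protocol.

What the fixture does **not** emulate: stain variability, magnification
structure, fine nuclear morphology, intra-class heterogeneity, or label
noise. The classes are separable by global color statistics, so passing
tests demonstrate that the optimizers and the evaluation pipeline work —
not that the architecture would reach any particular accuracy on real
histopathology.

## Study conditions for the end-to-end checks

The training scenarios run at a deliberately small scale chosen as this
package's reference conditions: 200 synthetic images (100 per class,
32×32, 8 patients, generator seed 0), split patient-wise at 0.7, and a
reduced network — two 4-filter conv layers, one pool, no hidden layer
(1,830 parameters). Adam trains for 300 iterations at batch 32; the GA
uses population 20, 8 parents, 200 generations at batch 128 (larger
evaluation batches suit the GA, which needs low-noise fitness to rank
members); gradient descent runs 300 iterations at batch 32 and is
checked for loss improvement only — at α = 0.001 it moves far too slowly
to fit in this budget, which reproduces the qualitative ordering
GD ≪ Adam ≈ GA seen at full scale.

At these conditions and seed 0, Adam and the GA both reach 1.00 training
accuracy and beat the untrained baseline on held-out patients. With the
*default* GA settings (population 40, batch 32) the realized final
training error at seed 0 is 0.28 — the mini-batch best-ever selection is
noisy at batch 32, which is consistent with the observation that the GA
needs larger batches.

## Numerical choices

- Float64 throughout; softmax is max-shifted, and the sigmoid is
  branch-evaluated so large |x| cannot overflow.
- Convolution uses `sliding_window_view` plus `tensordot` — the plain
  NumPy formulation of the patch dot product (no FFT or GEMM-scheduling
  machinery).
- Cross-entropy guards log(0) with a 1e−300 floor.
- Argmax ties go to class 0; sort-based selection is stable.
- Checkpoints are single-file `.npz` archives with the architecture
  embedded as JSON, written and read losslessly.

## Known limitations

- **GA seed sensitivity.** With single-gene-per-offspring mutation the
  GA explores ~1 gene change per offspring per generation; success at
  the 200-generation budget depends noticeably on the initial
  population. Across arbitrary seeds the GA's final training accuracy at
  the reference conditions ranges roughly from 0.7 to 1.0. This is a
  property of the algorithm as specified (selection and crossover do
  most of the work; mutation is a weak local search), not of the
  implementation.
- The GA evaluates the full forward pass for every member every
  generation; at full 210×210 scale this is orders of magnitude more
  compute per unit of progress than Adam, so large-scale runs need the
  CLI's checkpointing and patience.
- Plain mini-batch GD at the reference learning rate barely moves in
  300 iterations; it is a baseline, not a practical trainer here.
- The fixture's separability means test metrics saturate; comparisons of
  optimizer *quality* beyond "learns / does not learn" require real
  data.
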