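"""Generate a synthetic two-class histology-like dataset and inspect it.

Benign images carry a few large pale blobs on a pink background;
malignant images many small dark-purple blobs.  Patients are synthetic
and class-pure, so patient-wise splitting is meaningful.
"""

import numpy as np

from gacnn import generate_synthetic_dataset, split_patientwise

ds = generate_synthetic_dataset(n_per_class=50, image_size=32, n_patients=10, seed=0)
train, test = split_patientwise(ds, train_fraction=0.7, seed=0)

benign_blobs = [im.meta["blob_count"] for im in ds if im.label == 0]
malignant_blobs = [im.meta["blob_count"] for im in ds if im.label == 1]

print(f"dataset: {len(ds)} images, {len(ds.patients)} patients, "
      f"class counts {ds.class_counts}")
print(f"train/test: {len(train)}/{len(test)} images "
      f"({len(train.patients)}/{len(test.patients)} patients, disjoint: "
      f"{not set(train.patients) & set(test.patients)})")
print(f"mean blob count: benign {np.mean(benign_blobs):.1f}, "
      f"malignant {np.mean(malignant_blobs):.1f}")
# The blob-count and color contrast is what a classifier must pick up;
# the patient split guarantees it is scored on unseen patients.
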