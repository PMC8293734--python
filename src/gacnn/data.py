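"""Dataset handling: folder ingestion, patient-wise splitting, synthetic images.

Images follow the BreakHis-style filename grammar

    BIOPSY_CLASS_SUBTYPE-YEAR-SLIDE-MAG-SEQ.EXT
    e.g.  SOB_B_TA-14-4659-40-001.png

where CLASS is B (benign) or M (malignant), "YEAR-SLIDE" identifies the
patient, and MAG is the magnification factor.  Train/test splits are
patient-wise: no patient's images may appear on both sides, which is the
leakage-safe protocol for histopathology slides (many images per biopsy).

The synthetic generator emulates the two-class texture contrast of
hematoxylin/eosin-stained slides at a configurable resolution: benign
images carry a few large pale blobs on a pink-tinted background,
malignant images many small dark-purple blobs (hyperchromatic nuclei)
with a color shift and higher count variance.  Every training and
evaluation path of the package is exercisable on these images with no
downloads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LabeledImage",
    "Dataset",
    "parse_filename",
    "FilenameError",
    "read_image_folder",
    "split_patientwise",
    "generate_synthetic_dataset",
    "write_dataset_to_folder",
    "BENIGN",
    "MALIGNANT",
]

logger = logging.getLogger(__name__)

BENIGN, MALIGNANT = 0, 1
LABEL_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}

_FILENAME_RE = re.compile(
    r"^(?P<biopsy>[A-Za-z]+)_(?P<cls>[BM])_(?P<subtype>[A-Za-z0-9]+)"
    r"-(?P<year>\d+)-(?P<slide>[A-Za-z0-9]+)-(?P<mag>\d+)-(?P<seq>\d+)"
    r"\.(?P<ext>png|jpg|jpeg)$",
    re.IGNORECASE,
)


class FilenameError(ValueError):
    """Filename does not follow the BIOPSY_CLASS_SUBTYPE-YEAR-SLIDE-MAG-SEQ grammar."""


def parse_filename(name: str) -> tuple[int, str, int]:
    """Extract (label, patient_id, magnification) from a BreakHis-style name.

    >>> parse_filename("SOB_B_TA-14-4659-40-001.png")
    (0, '14-4659', 40)
    """
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise FilenameError(f"cannot parse filename {name!r}")
    label = BENIGN if m.group("cls").upper() == "B" else MALIGNANT
    patient_id = f"{m.group('year')}-{m.group('slide')}"
    return label, patient_id, int(m.group("mag"))


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) floats in [0, 1]
    label: int
    patient_id: str
    magnification: int
    source_name: str
    meta: dict = field(default_factory=dict)


class Dataset:
    """A list of labeled images with a patient index for leakage-safe splits."""

    def __init__(self, images: list[LabeledImage]):
        self.images = list(images)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    def __getitem__(self, i) -> LabeledImage:
        return self.images[i]

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {BENIGN: 0, MALIGNANT: 0}
        for img in self.images:
            counts[img.label] += 1
        return counts

    @property
    def patient_index(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for i, img in enumerate(self.images):
            idx.setdefault(img.patient_id, []).append(i)
        return idx

    @property
    def patients(self) -> list[str]:
        return sorted(self.patient_index)

    def subset(self, indices) -> "Dataset":
        return Dataset([self.images[i] for i in indices])

    def pixels_array(self) -> np.ndarray:
        """Stack all images into one (N, H, W, 3) array."""
        return np.stack([img.pixels for img in self.images])

    def labels_array(self) -> np.ndarray:
        return np.array([img.label for img in self.images], dtype=int)


def read_image_folder(root, target_size: int = 210) -> Dataset:
    """Load every parsable PNG/JPEG under ``root`` (flat or nested).

    Images are converted to RGB, bilinearly resized to
    ``target_size x target_size``, and scaled to [0, 1].  Files whose
    names do not follow the grammar (or that fail to decode) are skipped
    with a logged warning.  Traversal order is a stable sort by relative
    path, so re-reads are deterministic.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    paths = sorted(
        (p for p in root.rglob("*") if p.is_file()),
        key=lambda p: str(p.relative_to(root)),
    )
    images: list[LabeledImage] = []
    for p in paths:
        try:
            label, patient_id, mag = parse_filename(p.name)
        except FilenameError:
            logger.warning("skipping unparsable file %s", p.name)
            continue
        try:
            with Image.open(p) as im:
                im = im.convert("RGB").resize(
                    (target_size, target_size), Image.Resampling.BILINEAR
                )
                pixels = np.asarray(im, dtype=float) / 255.0
        except OSError as exc:
            logger.warning("skipping unreadable file %s (%s)", p.name, exc)
            continue
        images.append(LabeledImage(pixels, label, patient_id, mag, p.name))
    if not images:
        raise ValueError(f"no parsable images found under {root}")
    return Dataset(images)


def split_patientwise(
    dataset: Dataset, train_fraction: float = 0.7, seed: int | None = 0
) -> tuple[Dataset, Dataset]:
    """Split by patient, targeting ``train_fraction`` of the *images*.

    Patients are shuffled by the seed and assigned greedily to the
    training side until its image count first reaches the target
    fraction; the remaining patients form the test side.  No patient
    ever appears on both sides.  An exact 70/30 image split is generally
    impossible patient-wise, so the realized train fraction is >= the
    requested one.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    index = dataset.patient_index
    if len(index) < 2:
        raise ValueError("patient-wise splitting needs at least 2 patients")
    rng = np.random.default_rng(seed)
    patients = sorted(index)
    order = rng.permutation(len(patients))
    target = train_fraction * len(dataset)
    train_idx: list[int] = []
    test_idx: list[int] = []
    count = 0
    for pos in order:
        pid = patients[pos]
        if count < target:
            train_idx.extend(index[pid])
            count += len(index[pid])
        else:
            test_idx.extend(index[pid])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# synthetic two-class generator

# Background and blob colors approximating an H&E-stained slide: pink
# stroma with pale nuclei (benign) versus denser, darker purple nuclei
# (malignant).  The color shift plus blob density makes the classes
# cleanly separable, so the fixture is a meaningful test bed for all
# three trainers.
_BENIGN_BG = np.array([0.88, 0.72, 0.80])
_BENIGN_BLOB = np.array([0.96, 0.86, 0.92])
_MALIGNANT_BG = np.array([0.80, 0.62, 0.74])
_MALIGNANT_BLOB = np.array([0.40, 0.24, 0.52])


def _draw_blob_image(
    rng: np.random.Generator,
    size: int,
    bg: np.ndarray,
    blob_color: np.ndarray,
    n_blobs: int,
    r_lo: float,
    r_hi: float,
    noise_sd: float = 0.03,
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.ones((size, size, 3)) * bg
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(r_lo, r_hi)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        # soft alpha blend so overlapping blobs darken slightly
        img[mask] = 0.25 * img[mask] + 0.75 * blob_color
    img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    # quantize to 8 bits so a PNG write/read round trip is bitwise exact
    return np.round(img * 255.0) / 255.0


def generate_synthetic_dataset(
    n_per_class: int,
    image_size: int = 32,
    n_patients: int = 8,
    seed: int | None = 0,
    benign_mean_blobs: float = 6.0,
    malignant_mean_blobs: float = 25.0,
) -> Dataset:
    """Seeded two-class blob-texture dataset with fake patient IDs.

    Benign: ~``benign_mean_blobs`` (Poisson) large pale blobs.
    Malignant: ~``malignant_mean_blobs`` small dark blobs, with extra
    count variance (Poisson rate itself gamma-distributed).  Images are
    assigned round-robin to synthetic patients, patients split evenly
    between the classes (a patient has a single diagnosis).  Filenames
    follow the parser grammar, so writing and re-reading the folder
    recovers identical labels and patients.
    """
    if n_per_class <= 0 or image_size < 8:
        raise ValueError("need n_per_class >= 1 and image_size >= 8")
    if n_patients < 2:
        raise ValueError("need at least 2 patients (one per class)")
    rng = np.random.default_rng(seed)
    per_class_patients = max(1, n_patients // 2)
    images: list[LabeledImage] = []
    for label, cls_code in ((BENIGN, "B"), (MALIGNANT, "M")):
        for i in range(n_per_class):
            if label == BENIGN:
                n_blobs = max(1, int(rng.poisson(benign_mean_blobs)))
                px = _draw_blob_image(
                    rng, image_size, _BENIGN_BG, _BENIGN_BLOB, n_blobs,
                    0.12 * image_size, 0.22 * image_size,
                )
            else:
                rate = rng.gamma(4.0, malignant_mean_blobs / 4.0)
                n_blobs = max(1, int(rng.poisson(rate)))
                px = _draw_blob_image(
                    rng, image_size, _MALIGNANT_BG, _MALIGNANT_BLOB, n_blobs,
                    0.03 * image_size, 0.07 * image_size,
                )
            patient_no = i % per_class_patients
            patient_id = f"90-{cls_code}{patient_no:03d}"
            name = f"SOB_{cls_code}_SYN-90-{cls_code}{patient_no:03d}-40-{i + 1:03d}.png"
            images.append(
                LabeledImage(px, label, patient_id, 40, name, meta={"blob_count": n_blobs})
            )
    return Dataset(images)


def write_dataset_to_folder(dataset: Dataset, root) -> list[Path]:
    """Write every image as an 8-bit PNG named by its ``source_name``."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for img in dataset:
        arr = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
        path = root / img.source_name
        Image.fromarray(arr).save(path)
        written.append(path)
    return written
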