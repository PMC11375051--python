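"""Dataset loading, stratified splitting, resizing and train-set augmentation.

Metadata follows the HAM10000 dialect: a comma-separated table with an
``image_id`` column and a ``dx`` diagnosis column drawn from the seven-class
vocabulary {akiec, bcc, bkl, df, mel, nv, vasc}.  Images resolve as
``image_id`` plus a ``.jpg``/``.png`` extension next to the metadata.

The reference protocol splits 70%/30% stratified by class at image level
and augments only the training partition with random flips, rotation
(-60..60 deg), shear (-50..50 deg) and isotropic scaling (0.5..1.5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, warp

__all__ = [
    "CLASSES",
    "ImageRecord",
    "DatasetTable",
    "AugmentationSpec",
    "TrainConfig",
    "load_dataset",
    "stratified_split",
    "resize_image",
    "augment_train",
]

#: The closed seven-class diagnosis vocabulary, alphabetical.
CLASSES = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")

_IMAGE_EXTS = (".jpg", ".jpeg", ".png")


@dataclass
class ImageRecord:
    """One image with its diagnosis label and split assignment."""

    image_id: str
    pixels: np.ndarray
    label: str
    split: str = "unassigned"

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(
                f"unknown diagnosis label {self.label!r} for image "
                f"{self.image_id!r}; expected one of {CLASSES}"
            )
        if self.pixels is not None and np.asarray(self.pixels).size == 0:
            raise ValueError(f"empty pixel array for image {self.image_id!r}")


@dataclass
class DatasetTable:
    """An ordered collection of image records."""

    records: list = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_histogram(self) -> dict:
        hist = {c: 0 for c in CLASSES}
        for rec in self.records:
            hist[rec.label] += 1
        return {c: n for c, n in hist.items() if n > 0}

    @property
    def labels(self) -> list:
        return [rec.label for rec in self.records]

    @property
    def image_ids(self) -> list:
        return [rec.image_id for rec in self.records]

    def to_metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"image_id": self.image_ids, "dx": self.labels}
        )

    def write_metadata(self, path) -> None:
        self.to_metadata().to_csv(path, index=False)

    def write_split_assignment(self, path) -> None:
        pd.DataFrame(
            {"image_id": self.image_ids, "split": [r.split for r in self]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AugmentationSpec:
    """Random-augmentation ranges for the training partition.

    ``flip_range`` records the printed range associated with flipping in
    the reference protocol; flips themselves are binary and applied per
    axis with probability 0.5.
    """

    flip_horizontal: bool = True
    flip_vertical: bool = True
    flip_range: tuple = (-45.0, 45.0)
    scale_range: tuple = (0.5, 1.5)
    shear_range: tuple = (-50.0, 50.0)
    rotation_range: tuple = (-60.0, 60.0)
    copies_per_image: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("flip_range", "scale_range", "shear_range", "rotation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """CNN retraining hyperparameters (SGD with momentum)."""

    mini_batch: int = 10
    epochs: int = 40
    learning_rate: float = 0.001
    validation_frequency: int = 701
    momentum: float = 0.9
    optimizer: str = "sgdm"
    seed: int = 0

    def __post_init__(self):
        if min(self.mini_batch, self.epochs + 1, self.validation_frequency) <= 0:
            raise ValueError("mini_batch, validation_frequency must be positive; epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _resolve_image(image_dir: Path, image_id: str) -> Path:
    for ext in _IMAGE_EXTS:
        p = image_dir / f"{image_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no image file for id {image_id!r} under {image_dir} "
        f"(tried extensions {_IMAGE_EXTS})"
    )


def load_dataset(image_dir, metadata) -> DatasetTable:
    """Read a metadata table plus its image files into a DatasetTable.

    ``metadata`` is a path to a delimited file with columns ``image_id``
    and ``dx``, or an equivalent DataFrame.  Rows with unknown labels or
    missing files raise errors naming the offending row.
    """
    image_dir = Path(image_dir)
    if isinstance(metadata, (str, Path)):
        meta = pd.read_csv(metadata)
    else:
        meta = metadata.copy()
    for col in ("image_id", "dx"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")

    records = []
    for _, row in meta.iterrows():
        image_id, dx = str(row["image_id"]), str(row["dx"])
        if dx not in CLASSES:
            raise ValueError(
                f"unknown diagnosis label {dx!r} in metadata row for image "
                f"{image_id!r}; expected one of {CLASSES}"
            )
        path = _resolve_image(image_dir, image_id)
        pixels = np.asarray(Image.open(path).convert("RGB"))
        records.append(ImageRecord(image_id=image_id, pixels=pixels, label=dx))
    return DatasetTable(records=records)


def stratified_split(
    table: DatasetTable, train_frac: float = 0.70, seed: int = 0
) -> tuple:
    """Split per class into train/test partitions (round-half-up per class).

    Every class must have at least two records so both partitions are
    non-empty for it.  Deterministic given the seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    by_class: dict = {}
    for idx, rec in enumerate(table.records):
        by_class.setdefault(rec.label, []).append(idx)
    for label, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(
                f"class {label!r} has {len(idxs)} record(s); stratified "
                "splitting needs at least 2 per class"
            )
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        n = len(idxs)
        n_train = int(np.floor(train_frac * n + 0.5))  # round half up
        n_train = min(max(n_train, 1), n - 1)
        train_idx.extend(idxs[:n_train])
        test_idx.extend(idxs[n_train:])

    def build(indices, split):
        recs = [
            replace(table.records[i], split=split) for i in sorted(indices)
        ]
        return DatasetTable(records=recs)

    return build(train_idx, "train"), build(test_idx, "test")


def resize_image(record: ImageRecord, side: int = 224) -> ImageRecord:
    """Bilinear-resize a record's pixels to side x side x 3 (uint8).

    Grayscale inputs are replicated to three channels first.
    """
    px = np.asarray(record.pixels)
    if px.size == 0:
        raise ValueError("cannot resize an empty image")
    if px.ndim == 2:
        px = np.repeat(px[..., None], 3, axis=2)
    img = Image.fromarray(px.astype(np.uint8))
    out = img.resize((side, side), Image.BILINEAR)
    return replace(record, pixels=np.asarray(out))


def _record_rng(seed: int, image_id: str, copy: int) -> np.random.Generator:
    # per-(record, copy) stream so the same transform is drawn for a given
    # image id regardless of which stream's pixels are being augmented
    digest = hashlib.sha256(
        f"{seed}|{image_id}|{copy}".encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _augment_pixels(px: np.ndarray, rng, spec: AugmentationSpec) -> np.ndarray:
    h, w = px.shape[:2]
    rot = np.deg2rad(rng.uniform(*spec.rotation_range))
    shear = np.deg2rad(rng.uniform(*spec.shear_range))
    scale = rng.uniform(*spec.scale_range)
    flip_h = spec.flip_horizontal and rng.random() < 0.5
    flip_v = spec.flip_vertical and rng.random() < 0.5

    center = AffineTransform(translation=(-(w - 1) / 2, -(h - 1) / 2))
    core = AffineTransform(scale=scale, rotation=rot, shear=shear)
    back = AffineTransform(translation=((w - 1) / 2, (h - 1) / 2))
    tform = center + core + back

    out = px.astype(np.float64) / 255.0
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    out = warp(out, tform.inverse, mode="reflect", order=1)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def augment_train(train: DatasetTable, spec: AugmentationSpec) -> DatasetTable:
    """Append ``copies_per_image`` randomly transformed copies per record.

    Only the training partition may be augmented; copies keep their
    source's label and are tagged ``<image_id>_augK``.  Deterministic
    given ``spec.seed``; the transform drawn for a given (image_id, copy)
    depends only on the seed and the id, so parallel per-stream datasets
    sharing ids receive identical geometry.
    """
    for rec in train:
        if rec.split == "test":
            raise ValueError(
                f"augment_train called on a table containing test-split "
                f"record {rec.image_id!r}"
            )
    out = list(train.records)
    for rec in train:
        for k in range(spec.copies_per_image):
            rng = _record_rng(spec.seed, rec.image_id, k)
            px = _augment_pixels(np.asarray(rec.pixels), rng, spec)
            out.append(
                ImageRecord(
                    image_id=f"{rec.image_id}_aug{k}",
                    pixels=px,
                    label=rec.label,
                    split=rec.split,
                )
            )
    return DatasetTable(records=out)
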