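"""Synthetic 7-class dermoscopy-like image generator.

Real dermoscopy class signal mixes oriented texture (recoverable from
Gabor subbands) with spatial lesion shape and color (recoverable from
the original image).  The generator emulates exactly that split so every
pipeline stage is testable without external data:

* each class carries an oriented cosine grating at a class-specific
  (frequency, orientation) pair — orientations cycle through
  {0, 30, 45, 60, 90, 120, 150} degrees and frequencies alternate
  between the two bank scales (0.176, 0.25 cycles/pixel), so only the
  0- and 90-degree classes sit exactly on a bank filter;
* each class also carries an elliptical lesion blob with class-specific
  eccentricity, radius fraction and mean color on a noisy skin-toned
  background.

A mix weight w in [0, 1] scales the texture term by w and the lesion
term by (1 - w): w=1 gives texture-only class signal, w=0 lesion-only,
intermediate values make the two streams complementary.  Class
proportions can mirror the HAM10000 benchmark's printed imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from gaborderm.data import CLASSES, DatasetTable, ImageRecord

__all__ = [
    "SynthSpec",
    "generate_dataset",
    "imbalanced_proportions",
    "HAM10000_COUNTS",
    "write_dataset",
]

#: Printed class counts of the HAM10000 benchmark (10015 images total).
HAM10000_COUNTS = {
    "akiec": 327,
    "bcc": 514,
    "bkl": 1099,
    "df": 115,
    "mel": 1113,
    "nv": 6705,
    "vasc": 142,
}

_ORIENTATIONS = (0.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0)
_FREQUENCIES = (0.176, 0.25)
_BACKGROUND = np.array([200.0, 170.0, 150.0])  # skin-toned base
# distinct per-class lesion color shifts (R, G, B)
_LESION_COLORS = (
    (-70.0, -40.0, -10.0),
    (-20.0, -70.0, -40.0),
    (-50.0, -60.0, -60.0),
    (10.0, -40.0, -70.0),
    (-80.0, -70.0, -30.0),
    (-30.0, -20.0, -60.0),
    (40.0, -60.0, -30.0),
)
_TEXTURE_AMPLITUDE = 40.0  # 8-bit units at mix weight 1
_LESION_STRENGTH = 1.0


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; defaults are the desk-scale test profile."""

    n_per_class: int | None = 70
    class_proportions: dict | None = None
    n_total: int | None = None
    image_side: int = 64
    mix_weight: float = 0.5
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must be in [0, 1]")
        if self.class_proportions is not None:
            if self.n_total is None:
                raise ValueError(
                    "n_total is required with class_proportions"
                )
            missing = set(CLASSES) - set(self.class_proportions)
            if missing:
                raise ValueError(f"proportions missing classes {sorted(missing)}")
            total = sum(self.class_proportions[c] for c in CLASSES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"class proportions must sum to 1, got {total}"
                )
        elif self.n_per_class is None or self.n_per_class < 1:
            raise ValueError("n_per_class must be a positive integer")

    def class_counts(self) -> dict:
        if self.class_proportions is None:
            return {c: self.n_per_class for c in CLASSES}
        counts = {
            c: int(round(self.class_proportions[c] * self.n_total))
            for c in CLASSES
        }
        return {c: max(n, 1) for c, n in counts.items()}


def class_parameters() -> pd.DataFrame:
    """The fixed class-to-signal assignment used by the generator."""
    rows = []
    for i, c in enumerate(CLASSES):
        rows.append(
            {
                "label": c,
                "texture_orientation": _ORIENTATIONS[i],
                "texture_frequency": _FREQUENCIES[i % 2],
                "lesion_radius_frac": 0.14 + 0.03 * i,
                "lesion_eccentricity": 0.25 + 0.09 * i,
                "lesion_color_r": _LESION_COLORS[i][0],
                "lesion_color_g": _LESION_COLORS[i][1],
                "lesion_color_b": _LESION_COLORS[i][2],
            }
        )
    return pd.DataFrame(rows).set_index("label")


def imbalanced_proportions() -> dict:
    """Class proportions matching the HAM10000 benchmark's printed counts."""
    total = sum(HAM10000_COUNTS.values())
    return {c: HAM10000_COUNTS[c] / total for c in CLASSES}


def _render_image(params, side, mix, noise_sd, rng) -> np.ndarray:
    y, x = np.mgrid[0:side, 0:side].astype(float)
    img = _BACKGROUND[None, None, :] + rng.normal(
        0.0, noise_sd, size=(side, side, 3)
    )

    # oriented grating, luminance texture over the whole field
    th = np.deg2rad(params["texture_orientation"])
    phase = rng.uniform(0, 2 * np.pi)
    grating = np.cos(
        2 * np.pi * params["texture_frequency"]
        * (x * np.cos(th) + y * np.sin(th))
        + phase
    )
    img += mix * _TEXTURE_AMPLITUDE * grating[..., None]

    # elliptical lesion blob with jittered placement
    cx = side / 2 + rng.uniform(-0.06, 0.06) * side
    cy = side / 2 + rng.uniform(-0.06, 0.06) * side
    r = params["lesion_radius_frac"] * side * rng.uniform(0.85, 1.15)
    ecc = params["lesion_eccentricity"]
    b_axis = r * np.sqrt(1 - ecc**2)
    ang = rng.uniform(0, np.pi)
    dx, dy = x - cx, y - cy
    u = dx * np.cos(ang) + dy * np.sin(ang)
    v = -dx * np.sin(ang) + dy * np.cos(ang)
    dist2 = (u / r) ** 2 + (v / b_axis) ** 2
    mask = np.exp(-np.maximum(dist2 - 1.0, 0.0) * 8.0)  # soft-edged ellipse
    color = np.array([
        params["lesion_color_r"],
        params["lesion_color_g"],
        params["lesion_color_b"],
    ])
    img += (1.0 - mix) * _LESION_STRENGTH * mask[..., None] * color

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SynthSpec) -> tuple:
    """Generate a DatasetTable plus its ground-truth parameter table.

    Deterministic given ``spec.seed``; image ids encode the class and a
    running index.  The second return value records the class-level
    texture/lesion parameters so tests can assert recoverability.
    """
    rng = np.random.default_rng(spec.seed)
    params = class_parameters()
    records = []
    for c in CLASSES:
        row = params.loc[c]
        for i in range(spec.class_counts()[c]):
            px = _render_image(
                row, spec.image_side, spec.mix_weight, spec.noise_sd, rng
            )
            records.append(
                ImageRecord(image_id=f"{c}_{i:04d}", pixels=px, label=c)
            )
    truth = params.copy()
    truth["n_images"] = [spec.class_counts()[c] for c in CLASSES]
    truth["mix_weight"] = spec.mix_weight
    return DatasetTable(records=records), truth


def write_dataset(table: DatasetTable, out_dir, truth: pd.DataFrame | None = None):
    """Write PNG images plus metadata.csv in the loader's dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in table:
        Image.fromarray(rec.pixels).save(out_dir / f"{rec.image_id}.png")
    table.write_metadata(out_dir / "metadata.csv")
    if truth is not None:
        truth.to_csv(out_dir / "ground_truth.csv")
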