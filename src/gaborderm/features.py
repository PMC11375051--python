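"""Row-aligned deep-feature matrices and the two-stage fusion operations.

Each CNN branch emits a 7-dimensional feature vector per image (the
pre-softmax activations of its class head).  Fusion is columnwise
concatenation of row-aligned matrices: first the five streams of one
backbone (original + GW1..GW4 -> 35 columns), then across backbones
(3 backbones -> 105 columns).  Column provenance (backbone, stream,
unit index) is carried through so selections remain interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "fuse_streams", "fuse_backbones", "STREAMS"]

#: The five input streams of a branch ensemble.
STREAMS = ("original", "GW1", "GW2", "GW3", "GW4")


@dataclass
class FeatureMatrix:
    """samples x features matrix with row ids and per-column provenance.

    ``column_provenance[j]`` is a ``(backbone, stream, unit_index)`` triple.
    """

    values: np.ndarray
    row_ids: list
    column_provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length must equal the row count")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if len(self.column_provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal the column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            values=self.values[:, indices],
            row_ids=list(self.row_ids),
            column_provenance=[self.column_provenance[j] for j in indices],
        )

    def to_csv(self, path) -> None:
        """Write as delimited text with a 3-row provenance header."""
        prov = np.array(self.column_provenance, dtype=object).T
        with open(path, "w") as fh:
            fh.write("backbone," + ",".join(str(x) for x in prov[0]) + "\n")
            fh.write("stream," + ",".join(str(x) for x in prov[1]) + "\n")
            fh.write("unit," + ",".join(str(x) for x in prov[2]) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "," + ",".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        raw = pd.read_csv(path, header=None)
        backbones = raw.iloc[0, 1:].tolist()
        streams = raw.iloc[1, 1:].tolist()
        units = [int(u) for u in raw.iloc[2, 1:]]
        row_ids = raw.iloc[3:, 0].tolist()
        values = raw.iloc[3:, 1:].to_numpy(dtype=np.float64)
        prov = list(zip(backbones, streams, units))
        return cls(values=values, row_ids=row_ids, column_provenance=prov)


def _check_row_alignment(matrices) -> None:
    first = matrices[0].row_ids
    for m in matrices[1:]:
        if list(m.row_ids) != list(first):
            raise ValueError(
                "feature matrices are not row-aligned: row_ids differ "
                "(same ids in the same order are required before fusion)"
            )


def _concat(matrices) -> FeatureMatrix:
    return FeatureMatrix(
        values=np.hstack([m.values for m in matrices]),
        row_ids=list(matrices[0].row_ids),
        column_provenance=[
            p for m in matrices for p in m.column_provenance
        ],
    )


def fuse_streams(matrices) -> FeatureMatrix:
    """Concatenate the per-stream matrices of one backbone columnwise.

    All inputs must share row ids (same order) and the same backbone tag.
    Five 7-column inputs give the 35-column full fusion; the four GW
    streams alone give the 28-column all-GW variant.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to fuse")
    _check_row_alignment(matrices)
    backbones = {p[0] for m in matrices for p in m.column_provenance}
    if len(backbones) > 1:
        raise ValueError(
            f"fuse_streams expects a single backbone, got {sorted(backbones)}"
        )
    return _concat(matrices)


def fuse_backbones(matrices, expected_arity: int | None = 3) -> FeatureMatrix:
    """Concatenate per-backbone fused matrices columnwise.

    The reference pipeline fuses three backbones; pass ``expected_arity``
    to match the configured backbone count (``None`` disables the check).
    """
    matrices = list(matrices)
    if expected_arity is not None and len(matrices) != expected_arity:
        raise ValueError(
            f"fuse_backbones expected {expected_arity} matrices, "
            f"got {len(matrices)}"
        )
    if not matrices:
        raise ValueError("no matrices to fuse")
    _check_row_alignment(matrices)
    return _concat(matrices)
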