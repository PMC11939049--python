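"""Fixed-length vector encoding of records, with a dimension-to-feature map.

Each record becomes a single 1D vector: categorical features are one-hot
encoded per the schema vocabularies and concatenated, followed by the four
min-max-normalized numerical features.  The layout is:

* ``sequence`` — three positional slots (tripeptide length), each one-hot
  over the amino-acid vocabulary plus an explicit "absent" category that
  dipeptides use for the third slot;
* the seven single-valued categorical features — one one-hot block each;
* ``solution`` — a one-hot block over solvents plus a multi-hot block over
  the solute vocabulary (a record may carry several solutes);
* the numerical features — one dimension each, in [0, 1]; missing values
  are imputed with the feature's normalized median (recorded in the matrix
  metadata).

The :class:`FeatureGroupMap` records which contiguous span of vector
dimensions belongs to each of the 13 named features; grouped attribution
analyses sum importance values over these spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curation import normalize_features
from .dataset_model import (
    NUMERICAL_FEATURES,
    PeptideRecord,
    VocabularySchema,
)

#: vocabulary entry for the empty third residue slot of a dipeptide
ABSENT = "-"

MAX_SEQUENCE_LENGTH = 3


class EncodingError(ValueError):
    """A record carries a value absent from the encoding schema."""


@dataclass(frozen=True)
class FeatureGroupMap:
    """Maps each named feature to its contiguous [start, stop) span."""

    spans: dict[str, tuple[int, int]]

    @property
    def n_dims(self) -> int:
        return max(stop for _, stop in self.spans.values())

    def dims(self, feature: str) -> np.ndarray:
        start, stop = self.spans[feature]
        return np.arange(start, stop)

    def feature_names(self) -> list[str]:
        return sorted(self.spans, key=lambda f: self.spans[f][0])

    def validate(self) -> None:
        covered = np.zeros(self.n_dims, dtype=int)
        for start, stop in self.spans.values():
            covered[start:stop] += 1
        if not np.all(covered == 1):
            raise ValueError("feature spans must be disjoint and cover all dimensions")


@dataclass
class EncodedMatrix:
    """Model-ready design matrix with aligned phase labels."""

    X: np.ndarray
    y: np.ndarray  # phase labels (strings)
    group_map: FeatureGroupMap
    imputed_medians: dict[str, float] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]


def _schema_layout(schema: VocabularySchema) -> list[tuple[str, list[str]]]:
    """Ordered (block-name, categories) pairs for all one-hot blocks."""
    aa = list(schema.amino_acids) + [ABSENT]
    layout: list[tuple[str, list[str]]] = [
        (f"sequence[{i}]", aa) for i in range(MAX_SEQUENCE_LENGTH)
    ]
    for feat in VocabularySchema.SIMPLE_CATEGORICAL:
        layout.append((feat, schema.categories(feat)))
    layout.append(("solution.solvent", list(schema.solvents)))
    layout.append(("solution.solutes", list(schema.solutes)))
    return layout


def encoded_dim(schema: VocabularySchema) -> int:
    """Total vector length implied by a schema (one-hot blocks + 4 numerics)."""
    return sum(len(cats) for _, cats in _schema_layout(schema)) + len(
        NUMERICAL_FEATURES
    )


def _build_group_map(schema: VocabularySchema) -> FeatureGroupMap:
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    layout = _schema_layout(schema)
    # sequence: three slots form one feature span
    seq_width = sum(len(c) for name, c in layout if name.startswith("sequence["))
    spans["sequence"] = (pos, pos + seq_width)
    pos += seq_width
    for feat in VocabularySchema.SIMPLE_CATEGORICAL:
        width = len(schema.categories(feat))
        spans[feat] = (pos, pos + width)
        pos += width
    sol_width = len(schema.solvents) + len(schema.solutes)
    spans["solution"] = (pos, pos + sol_width)
    pos += sol_width
    for feat in NUMERICAL_FEATURES:
        spans[feat] = (pos, pos + 1)
        pos += 1
    gm = FeatureGroupMap(spans=spans)
    gm.validate()
    return gm


def _one_hot(value: str, categories: list[str], feature: str) -> np.ndarray:
    vec = np.zeros(len(categories))
    try:
        vec[categories.index(value)] = 1.0
    except ValueError:
        raise EncodingError(
            f"value {value!r} of feature {feature!r} is not in the schema "
            f"vocabulary {categories}"
        ) from None
    return vec


def encode_records(
    records: Sequence[PeptideRecord],
    schema: VocabularySchema,
    *,
    impute_medians: Optional[dict[str, float]] = None,
) -> tuple[EncodedMatrix, FeatureGroupMap]:
    """Encode records into an (n, D) matrix plus the feature-group map.

    Deterministic given the schema.  Numerics are normalized to [0, 1] per
    the schema ranges; missing values are imputed with the feature's
    normalized median over ``records`` (or with ``impute_medians`` when
    given, e.g. to reuse training-set medians at test time).
    """
    records = list(records)
    group_map = _build_group_map(schema)
    layout = _schema_layout(schema)
    n, D = len(records), encoded_dim(schema)
    X = np.zeros((n, D))

    numeric = normalize_features(records, schema)
    medians: dict[str, float] = {}
    for feat in NUMERICAL_FEATURES:
        if impute_medians and feat in impute_medians:
            medians[feat] = impute_medians[feat]
        else:
            med = float(np.nanmedian(numeric[feat])) if numeric[feat].notna().any() else 0.0
            medians[feat] = med

    for i, rec in enumerate(records):
        parts = []
        seq = list(rec.sequence) + [ABSENT] * (MAX_SEQUENCE_LENGTH - len(rec.sequence))
        for slot, (name, cats) in enumerate(layout[:MAX_SEQUENCE_LENGTH]):
            parts.append(_one_hot(seq[slot], cats, name))
        for feat in VocabularySchema.SIMPLE_CATEGORICAL:
            parts.append(_one_hot(getattr(rec, feat), schema.categories(feat), feat))
        parts.append(_one_hot(rec.solvent, list(schema.solvents), "solution.solvent"))
        multi = np.zeros(len(schema.solutes))
        for s in rec.solutes:
            try:
                multi[schema.solutes.index(s)] = 1.0
            except ValueError:
                raise EncodingError(
                    f"value {s!r} of feature 'solution.solutes' is not in the "
                    f"schema vocabulary {schema.solutes}"
                ) from None
        parts.append(multi)
        num = np.array(
            [
                medians[feat] if np.isnan(numeric[feat].iloc[i]) else numeric[feat].iloc[i]
                for feat in NUMERICAL_FEATURES
            ]
        )
        parts.append(num)
        X[i] = np.concatenate(parts)

    y = np.array([r.phase for r in records])
    matrix = EncodedMatrix(X=X, y=y, group_map=group_map, imputed_medians=medians)
    return matrix, group_map


def decode_vector(
    v: np.ndarray, group_map: FeatureGroupMap, schema: VocabularySchema
) -> dict:
    """Recover a partial record (field dict) from one encoded vector.

    Categorical fields are recovered exactly; numerics to normalization
    precision.  An all-zero one-hot block decodes to ``None`` ("unknown").
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (group_map.n_dims,):
        raise ValueError(
            f"vector of length {v.shape} does not match map dimension "
            f"{group_map.n_dims}"
        )

    def read_block(offset: int, cats: list[str]) -> Optional[str]:
        block = v[offset : offset + len(cats)]
        idx = np.flatnonzero(block == 1.0)
        return cats[idx[0]] if idx.size == 1 else None

    out: dict = {}
    aa = list(schema.amino_acids) + [ABSENT]
    start, _ = group_map.spans["sequence"]
    seq = []
    for slot in range(MAX_SEQUENCE_LENGTH):
        code = read_block(start + slot * len(aa), aa)
        if code is not None and code != ABSENT:
            seq.append(code)
    out["sequence"] = "".join(seq) if seq else None

    for feat in VocabularySchema.SIMPLE_CATEGORICAL:
        out[feat] = read_block(group_map.spans[feat][0], schema.categories(feat))

    sol_start, _ = group_map.spans["solution"]
    out["solvent"] = read_block(sol_start, list(schema.solvents))
    solute_block = v[
        sol_start + len(schema.solvents) : sol_start + len(schema.solvents) + len(schema.solutes)
    ]
    out["solutes"] = tuple(
        schema.solutes[j] for j in np.flatnonzero(solute_block == 1.0)
    )

    for feat in NUMERICAL_FEATURES:
        x = v[group_map.spans[feat][0]]
        if feat in schema.numeric_ranges:
            lo, hi = schema.numeric_ranges[feat]
            out[feat] = float(x * (hi - lo) + lo)
        else:
            out[feat] = float(x)
    return out
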