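"""Experimental records of short-peptide self-assembly and their controlled vocabularies.

A :class:`PeptideRecord` is one standardized data entry derived from a
publication: a di- or tripeptide sequence, its chemical modifications, the
solution environment, the numeric experimental conditions, and the observed
self-assembly phase.  Records are validated on construction; a curated
dataset is a list of records plus the publication each came from.

A :class:`VocabularySchema` holds the controlled category list for every
categorical feature and the (min, max) range of every numerical feature.
It is either built from data (:func:`build_vocabularies`) or loaded from
disk, and it fully determines the one-hot encoding dimensionality used by
:mod:`pepmine.encoding`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import ClassVar, Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: 1-letter codes of the 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The eight self-assembly phases modelled, including the non-assembly case.
PHASES = (
    "no-assembly",
    "hydrogel",
    "fiber",
    "tube",
    "sphere",
    "particle",
    "ribbon",
    "vesicle",
)

SYSTEM_CATEGORIES = ("peptide", "conjugate", "mixture")
THERMAL_PROCESSES = ("none", "heating", "cooling")
TOPOLOGIES = ("linear", "cyclic")

#: The nine categorical features of the record template.  "sequence" and
#: "solution" are multi-element features (positional residues; solvent plus
#: solutes); the rest are single-valued.
CATEGORICAL_FEATURES = (
    "sequence",
    "n_term_mod",
    "c_term_mod",
    "nonterm_mod",
    "system_category",
    "conjugate_partner",
    "thermal_process",
    "topology",
    "solution",
)

#: The four numerical features (units: volume fraction, mg/ml, pH units, deg C).
NUMERICAL_FEATURES = ("solvent_ratio", "concentration", "ph", "temperature")

ALL_FEATURES = CATEGORICAL_FEATURES + NUMERICAL_FEATURES

#: Token used on disk for a missing numeric value.
MISSING_TOKEN = "nan"

#: Delimiter for multi-solute "solution" fields in flat files.
SOLUTE_DELIMITER = ";"


class RecordValidationError(ValueError):
    """A row or record violated the dataset template."""


class PeptideRecord(BaseModel):
    """One standardized experimental data entry.

    Numeric fields may be ``None`` (missing); categorical fields always carry
    a label, with ``"none"`` meaning the absence of a modification, partner or
    solute.
    """

    model_config = ConfigDict(frozen=True)

    sequence: str
    n_term_mod: str = "none"
    c_term_mod: str = "none"
    nonterm_mod: str = "none"
    system_category: Literal["peptide", "conjugate", "mixture"] = "peptide"
    conjugate_partner: str = "none"
    thermal_process: Literal["none", "heating", "cooling"] = "none"
    topology: Literal["linear", "cyclic"] = "linear"
    solvent: str = "water"
    solutes: tuple[str, ...] = ()
    solvent_ratio: Optional[float] = 1.0
    concentration: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None
    phase: str
    source_id: str = ""

    @field_validator("sequence")
    @classmethod
    def _check_sequence(cls, v: str) -> str:
        v = v.strip().upper()
        if len(v) not in (2, 3):
            raise ValueError(
                f"sequence {v!r} has length {len(v)}; only dipeptides and "
                "tripeptides (length 2 or 3) are supported"
            )
        bad = [c for c in v if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(
                f"sequence {v!r} contains non-standard amino-acid code(s) {bad}"
            )
        return v

    @field_validator("phase")
    @classmethod
    def _check_phase(cls, v: str) -> str:
        v = v.strip().lower()
        if v not in PHASES:
            raise ValueError(
                f"unknown phase {v!r}; expected one of {sorted(PHASES)}"
            )
        return v

    @field_validator("solutes", mode="before")
    @classmethod
    def _split_solutes(cls, v):
        if v is None:
            return ()
        if isinstance(v, str):
            v = [s for s in v.split(SOLUTE_DELIMITER) if s.strip()]
        cleaned = tuple(
            s.strip() for s in v if s.strip() and s.strip().lower() != "none"
        )
        return cleaned

    @field_validator("solvent_ratio")
    @classmethod
    def _check_ratio(cls, v):
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"solvent_ratio {v} outside [0, 1]")
        return v

    @field_validator("concentration")
    @classmethod
    def _check_concentration(cls, v):
        if v is not None and v <= 0:
            raise ValueError(f"concentration {v} must be > 0 mg/ml")
        return v

    @field_validator("ph")
    @classmethod
    def _check_ph(cls, v):
        if v is not None and not (0.0 <= v <= 14.0):
            raise ValueError(f"pH {v} outside [0, 14]")
        return v

    @field_validator("solvent_ratio", "concentration", "ph", "temperature", mode="before")
    @classmethod
    def _missing_numeric(cls, v):
        if isinstance(v, str):
            v = v.strip()
            if v == "" or v.lower() == MISSING_TOKEN:
                return None
            return float(v)
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    @model_validator(mode="after")
    def _check_conjugate(self):
        has_partner = self.conjugate_partner != "none"
        if (self.system_category == "conjugate") != has_partner:
            raise ValueError(
                "system_category 'conjugate' requires a conjugate_partner and "
                f"vice versa (got category={self.system_category!r}, "
                f"partner={self.conjugate_partner!r})"
            )
        return self

    @property
    def solution(self) -> tuple[str, tuple[str, ...]]:
        """The composite 'solution' feature: (solvent, solutes)."""
        return (self.solvent, self.solutes)

    def numeric(self, feature: str) -> Optional[float]:
        if feature not in NUMERICAL_FEATURES:
            raise KeyError(f"{feature!r} is not a numerical feature")
        return getattr(self, feature)

    def to_row(self) -> dict:
        """Flat dict for CSV serialization; missing numerics become 'nan'."""
        row = {
            "sequence": self.sequence,
            "n_term_mod": self.n_term_mod,
            "c_term_mod": self.c_term_mod,
            "nonterm_mod": self.nonterm_mod,
            "system_category": self.system_category,
            "conjugate_partner": self.conjugate_partner,
            "thermal_process": self.thermal_process,
            "topology": self.topology,
            "solvent": self.solvent,
            "solutes": SOLUTE_DELIMITER.join(self.solutes),
            "phase": self.phase,
            "source_id": self.source_id,
        }
        for feat in NUMERICAL_FEATURES:
            v = getattr(self, feat)
            row[feat] = MISSING_TOKEN if v is None else repr(float(v))
        return row


#: Column order of the flat-file representation.
COLUMNS = (
    "sequence",
    "n_term_mod",
    "c_term_mod",
    "nonterm_mod",
    "system_category",
    "conjugate_partner",
    "thermal_process",
    "topology",
    "solvent",
    "solutes",
    "solvent_ratio",
    "concentration",
    "ph",
    "temperature",
    "phase",
    "source_id",
)


class ValidationReport(BaseModel):
    """Rows that failed validation, with position and reason."""

    failures: list[tuple[int, str]] = []

    @property
    def ok(self) -> bool:
        return not self.failures

    def __str__(self) -> str:  # human-readable summary
        if self.ok:
            return "all rows valid"
        lines = [f"{len(self.failures)} invalid row(s):"]
        lines += [f"  row {i}: {msg}" for i, msg in self.failures]
        return "\n".join(lines)


def _record_from_row(row: dict) -> PeptideRecord:
    known = {k: v for k, v in row.items() if k in COLUMNS}
    return PeptideRecord(**known)


def load_records(
    path: str | Path,
    format: Optional[Literal["csv", "json"]] = None,
    strict: bool = True,
) -> tuple[list[PeptideRecord], ValidationReport]:
    """Read a dataset of records from CSV or JSON.

    Parameters
    ----------
    path:
        File to read.  ``format`` defaults to the file suffix.
    strict:
        If True (default) raise :class:`RecordValidationError` on the first
        invalid row, naming the row and the offending value.  If False,
        invalid rows are collected in the returned report and skipped.

    Returns
    -------
    (records, report)
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = frame.to_dict(orient="records")
    else:
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise RecordValidationError("JSON dataset must be an array of objects")

    records: list[PeptideRecord] = []
    failures: list[tuple[int, str]] = []
    for i, row in enumerate(rows):
        try:
            records.append(_record_from_row(dict(row)))
        except Exception as exc:  # pydantic ValidationError or ours
            if hasattr(exc, "errors"):
                msg = "; ".join(e["msg"] for e in exc.errors())
            else:
                msg = str(exc)
            if strict:
                raise RecordValidationError(f"row {i}: {msg}") from exc
            failures.append((i, msg))
    return records, ValidationReport(failures=failures)


def write_records(
    records: Sequence[PeptideRecord],
    path: str | Path,
    format: Optional[Literal["csv", "json"]] = None,
) -> Path:
    """Write records to CSV or JSON such that :func:`load_records` round-trips."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    rows = [r.to_row() for r in records]
    if fmt == "csv":
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        frame.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(rows, indent=1))
    return path


class VocabularySchema(BaseModel):
    """Controlled vocabularies and numeric ranges derived from a dataset.

    Category lists are lexicographically sorted so that encodings are
    reproducible regardless of record order.
    """

    amino_acids: list[str]
    n_term_mod: list[str]
    c_term_mod: list[str]
    nonterm_mod: list[str]
    system_category: list[str]
    conjugate_partner: list[str]
    thermal_process: list[str]
    topology: list[str]
    solvents: list[str]
    solutes: list[str]
    numeric_ranges: dict[str, tuple[float, float]]

    #: single-valued categorical features -> their schema attribute
    SIMPLE_CATEGORICAL: ClassVar[tuple[str, ...]] = (
        "n_term_mod",
        "c_term_mod",
        "nonterm_mod",
        "system_category",
        "conjugate_partner",
        "thermal_process",
        "topology",
    )

    def categories(self, feature: str) -> list[str]:
        if feature in self.SIMPLE_CATEGORICAL:
            return list(getattr(self, feature))
        raise KeyError(feature)

    def numeric_range(self, feature: str) -> tuple[float, float]:
        return self.numeric_ranges[feature]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "VocabularySchema":
        return cls.model_validate_json(Path(path).read_text())


def build_vocabularies(records: Iterable[PeptideRecord]) -> VocabularySchema:
    """Derive the vocabulary schema from observed records.

    Every observed categorical value appears exactly once in its feature's
    (sorted) list; numeric (min, max) are the observed extremes, ignoring
    missing values.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build vocabularies from an empty record list")

    def uniq(values: Iterable[str]) -> list[str]:
        return sorted(set(values))

    ranges: dict[str, tuple[float, float]] = {}
    for feat in NUMERICAL_FEATURES:
        observed = [getattr(r, feat) for r in records if getattr(r, feat) is not None]
        if observed:
            ranges[feat] = (float(min(observed)), float(max(observed)))

    return VocabularySchema(
        amino_acids=uniq(c for r in records for c in r.sequence),
        n_term_mod=uniq(r.n_term_mod for r in records),
        c_term_mod=uniq(r.c_term_mod for r in records),
        nonterm_mod=uniq(r.nonterm_mod for r in records),
        system_category=uniq(r.system_category for r in records),
        conjugate_partner=uniq(r.conjugate_partner for r in records),
        thermal_process=uniq(r.thermal_process for r in records),
        topology=uniq(r.topology for r in records),
        solvents=uniq(r.solvent for r in records),
        solutes=uniq(s for r in records for s in r.solutes),
        numeric_ranges=ranges,
    )
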