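"""Standardization rules that turn reported experimental descriptions into data entries.

Curation of the literature follows five conventions:

1. a condition reported as a *range* is expanded into six evenly spaced
   entries covering the range, endpoints included;
2. a reported *critical value* of a phase transition is bracketed by four
   entries, at 0.8x and 0.9x of the critical value (labelled with the phase
   below the transition) and at 1.1x and 1.2x (phase above);
3. peptide concentrations are standardized to mg/ml, converting molar units
   via the peptide's molecular weight;
4. a missing pH may be resolved from the solution composition (pluggable
   resolver; by default only pure water resolves, to pH 7);
5. a missing temperature defaults to room temperature, 25 degrees C.

Numeric features are min-max normalized to [0, 1] at the model boundary
(:func:`normalize_features`); records themselves keep raw units.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset_model import (
    NUMERICAL_FEATURES,
    PHASES,
    PeptideRecord,
    VocabularySchema,
)

#: Average residue masses (g/mol) of the 20 standard amino acids: the mass
#: contributed by each residue inside a chain (free amino acid minus water).
RESIDUE_MASSES = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

WATER_MASS = 18.02


def molecular_weight(sequence: str, extra_mass: float = 0.0) -> float:
    """Average molecular weight (g/mol) of an unmodified linear peptide.

    Sum of residue masses plus one water (the chain's free termini).
    ``extra_mass`` can account for modifications when their mass is known.
    """
    sequence = sequence.strip().upper()
    try:
        total = sum(RESIDUE_MASSES[c] for c in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid code {exc.args[0]!r} in {sequence!r}")
    return total + WATER_MASS + extra_mass


@dataclass(frozen=True)
class RangeSpec:
    """A reported parameter range to be expanded into discrete entries."""

    feature: str
    low: float
    high: float

    def __post_init__(self):
        if self.feature not in NUMERICAL_FEATURES:
            raise ValueError(f"{self.feature!r} is not a numerical feature")
        if not self.low < self.high:
            raise ValueError(f"range requires low < high (got {self.low}, {self.high})")


@dataclass(frozen=True)
class CriticalTransition:
    """A reported critical value separating two phases along one feature."""

    feature: str
    critical: float
    phase_below: str
    phase_above: str

    def __post_init__(self):
        if self.feature not in NUMERICAL_FEATURES:
            raise ValueError(f"{self.feature!r} is not a numerical feature")
        if self.critical <= 0:
            raise ValueError(f"critical value must be > 0 (got {self.critical})")
        for p in (self.phase_below, self.phase_above):
            if p not in PHASES:
                raise ValueError(f"unknown phase {p!r}")
        if self.phase_below == self.phase_above:
            raise ValueError("phases below and above the transition must differ")


N_RANGE_SAMPLES = 6
BRACKET_MULTIPLIERS_BELOW = (0.8, 0.9)
BRACKET_MULTIPLIERS_ABOVE = (1.1, 1.2)


def expand_range(spec: RangeSpec, template: PeptideRecord) -> list[PeptideRecord]:
    """Expand a parameter range into six evenly spaced entries (rule 1).

    The ranged feature takes values ``linspace(low, high, 6)`` (endpoints
    included); all other fields are copied from ``template``.
    """
    values = np.linspace(spec.low, spec.high, N_RANGE_SAMPLES)
    return [
        template.model_copy(update={spec.feature: float(v)}) for v in values
    ]


def bracket_critical(
    t: CriticalTransition, template: PeptideRecord
) -> list[PeptideRecord]:
    """Bracket a critical phase-transition value with four entries (rule 2).

    Two entries at 0.8c and 0.9c carry ``phase_below``; two at 1.1c and 1.2c
    carry ``phase_above``.
    """
    out = []
    for m in BRACKET_MULTIPLIERS_BELOW:
        out.append(
            template.model_copy(
                update={t.feature: float(m * t.critical), "phase": t.phase_below}
            )
        )
    for m in BRACKET_MULTIPLIERS_ABOVE:
        out.append(
            template.model_copy(
                update={t.feature: float(m * t.critical), "phase": t.phase_above}
            )
        )
    return out


_UNIT_ALIASES = {
    "mg/ml": "mg/ml",
    "mg/mL": "mg/ml",
    "mg ml-1": "mg/ml",
    "mm": "mM",
    "mM": "mM",
    "um": "uM",
    "uM": "uM",
    "µm": "uM",  # µM
    "µM": "uM",
    "wt%": "wt%",
    "wt %": "wt%",
    "%w/v": "%w/v",
    "% w/v": "%w/v",
}


def parse_quantity(text: str) -> tuple[float, str]:
    """Parse a reported concentration like ``"10 mM"`` into (value, unit)."""
    m = re.match(r"\s*([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*(.+?)\s*$", text)
    if not m:
        raise ValueError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2).strip()
    key = unit if unit in _UNIT_ALIASES else unit.lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return value, _UNIT_ALIASES[key]


def concentration_to_mg_ml(
    value: float,
    unit: str,
    sequence: str,
    *,
    mw: Optional[float] = None,
    solution_density_mg_ml: float = 1000.0,
) -> float:
    """Convert a reported peptide concentration to mg/ml (rule 3).

    Molar units use the peptide molecular weight (computed from the sequence
    unless ``mw`` is given).  Weight-percent assumes the given solution
    density (water by default).
    """
    key = unit if unit in _UNIT_ALIASES else unit.lower()
    if key not in _UNIT_ALIASES:
        raise ValueError(f"unknown concentration unit {unit!r}")
    unit = _UNIT_ALIASES[key]
    if unit == "mg/ml":
        return value
    if unit in ("mM", "uM"):
        weight = mw if mw is not None else molecular_weight(sequence)
        molar_mM = value if unit == "mM" else value / 1000.0
        return molar_mM * weight / 1000.0  # mmol/l * g/mol / 1000 = mg/ml
    if unit == "wt%":
        return value / 100.0 * solution_density_mg_ml
    if unit == "%w/v":
        return value * 10.0  # 1 % w/v = 10 mg/ml
    raise ValueError(f"unknown concentration unit {unit!r}")


#: A pH resolver maps (solvent, solutes, solvent_ratio) -> pH or None.
PhResolver = Callable[[str, Sequence[str], Optional[float]], Optional[float]]


def default_ph_resolver(
    solvent: str, solutes: Sequence[str], solvent_ratio: Optional[float]
) -> Optional[float]:
    """Resolve pH from the solution composition (rule 4).

    Only the unambiguous case is resolved: pure water with no solutes is
    pH 7.  Mixed solvents and solutions with solutes stay unresolved (the
    record keeps a missing pH).
    """
    if solvent.strip().lower() == "water" and not solutes and (
        solvent_ratio is None or solvent_ratio == 1.0
    ):
        return 7.0
    return None


ROOM_TEMPERATURE_C = 25.0


def standardize_record(
    record: PeptideRecord,
    reported_concentration: Optional[str] = None,
    *,
    ph_resolver: PhResolver = default_ph_resolver,
    mw: Optional[float] = None,
) -> PeptideRecord:
    """Apply curation rules 3-5 to one record.

    ``reported_concentration`` is a value+unit string (e.g. ``"2 mM"``);
    when given it overrides the record's concentration after conversion to
    mg/ml.  A missing temperature becomes 25 C; a missing pH is passed to
    the resolver.
    """
    updates: dict = {}
    if reported_concentration is not None:
        value, unit = parse_quantity(reported_concentration)
        updates["concentration"] = concentration_to_mg_ml(
            value, unit, record.sequence, mw=mw
        )
    if record.temperature is None:
        updates["temperature"] = ROOM_TEMPERATURE_C
    if record.ph is None:
        resolved = ph_resolver(record.solvent, record.solutes, record.solvent_ratio)
        if resolved is not None:
            updates["ph"] = resolved
    return record.model_copy(update=updates) if updates else record


def normalize_features(
    records: Sequence[PeptideRecord], schema: VocabularySchema
) -> pd.DataFrame:
    """Min-max normalize the four numeric features to [0, 1].

    Returns a DataFrame (one row per record, one column per numeric feature)
    with ``x -> (x - min) / (max - min)`` per the schema's observed ranges.
    Missing values propagate as NaN.  A feature with zero spread maps to 0
    with a warning.
    """
    out = {}
    for feat in NUMERICAL_FEATURES:
        raw = np.array(
            [np.nan if r.numeric(feat) is None else r.numeric(feat) for r in records],
            dtype=float,
        )
        if feat not in schema.numeric_ranges:
            out[feat] = np.full_like(raw, np.nan)
            continue
        lo, hi = schema.numeric_ranges[feat]
        if hi == lo:
            warnings.warn(
                f"feature {feat!r} has zero spread (min == max == {lo}); mapped to 0"
            )
            out[feat] = np.where(np.isnan(raw), np.nan, 0.0)
        else:
            out[feat] = (raw - lo) / (hi - lo)
    return pd.DataFrame(out, columns=list(NUMERICAL_FEATURES))


def denormalize(values: pd.DataFrame, schema: VocabularySchema) -> pd.DataFrame:
    """Inverse of :func:`normalize_features` for features with nonzero spread."""
    out = {}
    for feat in values.columns:
        if feat not in schema.numeric_ranges:
            out[feat] = np.full(len(values), np.nan)
            continue
        lo, hi = schema.numeric_ranges[feat]
        out[feat] = values[feat] * (hi - lo) + lo
    return pd.DataFrame(out, columns=list(values.columns))
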