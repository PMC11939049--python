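"""Scoring extracted records against ground truth: exact-match accuracy + MAE.

The matching protocol pairs each predicted entry with a ground-truth entry
from the same publication:

1. an exact, unique match on (sequence, phase) pairs directly;
2. otherwise the prediction is paired with the remaining truth entry that
   agrees on the most of the other 11 features (ties broken by lowest
   truth-entry index); each truth entry is consumed at most once.

Scoring then reports, per categorical feature, the fraction of pairs whose
values fully align (the composite "solution" feature counts as correct
only when solvent AND solutes all match), and per numerical feature the
mean absolute error in raw units over pairs where both sides carry a
value — missing ("nan") extractions are excluded from the MAE and tallied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .dataset_model import NUMERICAL_FEATURES, PeptideRecord

#: The nine categorical features as scored; "solution" is the composite
#: (solvent, solutes) and the others are single fields.
CATEGORICAL_SCORED = (
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

#: Features other than sequence and phase, used by the fallback matcher.
SECONDARY_FEATURES = tuple(
    f for f in CATEGORICAL_SCORED if f != "sequence"
) + NUMERICAL_FEATURES

Entry = Union[dict, PeptideRecord]


def _get(entry: Entry, feature: str):
    """Read one feature off a prediction dict or a PeptideRecord."""
    if isinstance(entry, PeptideRecord):
        if feature == "solution":
            return entry.solution
        return getattr(entry, feature if feature != "ph" else "ph")
    if feature == "solution":
        solutes = entry.get("solutes") or ()
        return (entry.get("solvent"), tuple(solutes))
    return entry.get(feature)


def _norm_cat(value) -> Optional[object]:
    if value is None:
        return None
    if isinstance(value, tuple):
        head, solutes = value
        if head is None:
            return None
        return (str(head).lower(), tuple(sorted(str(s).lower() for s in solutes)))
    v = str(value).strip().lower()
    return v if v and v != "nan" else None


def _agree(pred: Entry, truth: Entry, feature: str) -> bool:
    if feature in NUMERICAL_FEATURES:
        p, t = _get(pred, feature), _get(truth, feature)
        if p is None or t is None:
            return p is None and t is None
        return math.isclose(float(p), float(t), rel_tol=1e-6, abs_tol=1e-9)
    return _norm_cat(_get(pred, feature)) == _norm_cat(_get(truth, feature))


@dataclass
class Pairing:
    """Prediction/truth pairs plus the predictions left unmatched."""

    pairs: list[tuple[Entry, Entry]] = field(default_factory=list)
    unmatched_predictions: list[Entry] = field(default_factory=list)
    unused_truth: list[Entry] = field(default_factory=list)


def match_entries(
    predicted: Sequence[Entry], truth: Sequence[Entry]
) -> Pairing:
    """Pair predicted entries with ground-truth entries of the same paper."""
    remaining = list(range(len(truth)))
    pairs: list[tuple[Entry, Entry]] = []
    unmatched: list[Entry] = []

    for pred in predicted:
        if not remaining:
            unmatched.append(pred)
            continue
        # step 1: exact, unique (sequence, phase) match
        key = (_norm_cat(_get(pred, "sequence")), _norm_cat(_get(pred, "phase")))
        exact = [
            j
            for j in remaining
            if key[0] is not None
            and key[1] is not None
            and (_norm_cat(_get(truth[j], "sequence")), _norm_cat(_get(truth[j], "phase"))) == key
        ]
        if len(exact) == 1:
            j = exact[0]
        else:
            # step 2: most agreement over the remaining 11 features among
            # the candidates (all remaining truth entries when no or
            # multiple direct matches); lowest index wins ties
            candidates = exact if len(exact) > 1 else remaining
            j = max(
                candidates,
                key=lambda jj: (
                    sum(_agree(pred, truth[jj], f) for f in SECONDARY_FEATURES),
                    -jj,
                ),
            )
        remaining.remove(j)
        pairs.append((pred, truth[j]))

    return Pairing(
        pairs=pairs,
        unmatched_predictions=unmatched,
        unused_truth=[truth[j] for j in remaining],
    )


@dataclass
class MatchReport:
    """Per-feature extraction scores.

    ``categorical_accuracy`` maps each of the 9 categorical features to its
    exact-match fraction; ``numeric_mae`` maps each numerical feature to its
    MAE in raw units (mg/ml, pH units, deg C, volume fraction), or None when
    no comparable pair existed.
    """

    categorical_accuracy: dict[str, Optional[float]]
    numeric_mae: dict[str, Optional[float]]
    n_pairs: int
    n_unmatched_predictions: int
    n_unused_truth: int
    numeric_excluded: dict[str, int]
    numeric_used: dict[str, int]

    @property
    def mean_categorical_accuracy(self) -> Optional[float]:
        """Unweighted mean over the 9 categorical features (defined ones)."""
        vals = [v for v in self.categorical_accuracy.values() if v is not None]
        return sum(vals) / len(vals) if vals else None


def score_pairs(pairing: Pairing) -> MatchReport:
    """Score a pairing into per-feature accuracies and MAEs."""
    pairs = pairing.pairs
    cat_acc: dict[str, Optional[float]] = {}
    for feat in CATEGORICAL_SCORED:
        if not pairs:
            cat_acc[feat] = None  # undefined, not zero
            continue
        cat_acc[feat] = sum(_agree(p, t, feat) for p, t in pairs) / len(pairs)

    mae: dict[str, Optional[float]] = {}
    excluded: dict[str, int] = {}
    used: dict[str, int] = {}
    for feat in NUMERICAL_FEATURES:
        errors = []
        n_excl = 0
        for p, t in pairs:
            pv, tv = _get(p, feat), _get(t, feat)
            if pv is None or tv is None:
                n_excl += 1
                continue
            errors.append(abs(float(pv) - float(tv)))
        excluded[feat] = n_excl
        used[feat] = len(errors)
        mae[feat] = sum(errors) / len(errors) if errors else None

    return MatchReport(
        categorical_accuracy=cat_acc,
        numeric_mae=mae,
        n_pairs=len(pairs),
        n_unmatched_predictions=len(pairing.unmatched_predictions),
        n_unused_truth=len(pairing.unused_truth),
        numeric_excluded=excluded,
        numeric_used=used,
    )


def score_extraction(
    predicted: Sequence[Entry], truth: Sequence[Entry]
) -> MatchReport:
    """Convenience: match then score in one call."""
    return score_pairs(match_entries(predicted, truth))
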