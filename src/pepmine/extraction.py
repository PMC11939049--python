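"""Entity extraction of the 13 experimental features (+ phase) from processed text.

Extraction is a named-entity task: given preprocessed publication text, pull
out every experimental data entry (a publication usually reports several)
as a flat field->string map, using the missing marker ``"nan"`` for
anything the text does not state.  Backends are pluggable; the shipped
reference backend is rule-based (regular-expression patterns over
sample-anchored sentences) and fully deterministic, which makes it the
ceiling-measuring instrument for the evaluation harness.  A remote
language-model backend can be registered through the same contract but is
never required.

:func:`coerce_fields` normalizes raw backend strings against the dataset
schema: unit-bearing quantities are standardized (mg/ml), spelling variants
are mapped through an alias table, and anything unmappable becomes the
missing marker — out-of-vocabulary values can never reach storage.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence

from .curation import concentration_to_mg_ml, parse_quantity
from .dataset_model import (
    AMINO_ACIDS,
    MISSING_TOKEN,
    PHASES,
    PeptideRecord,
    SOLUTE_DELIMITER,
    VocabularySchema,
)

logger = logging.getLogger(__name__)

#: Field names a backend may emit (the 13 features, solution split into
#: solvent/solutes, plus the phase).
ENTITY_FIELDS = (
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
)


class ExtractionBackend(Protocol):
    """Contract every extraction backend satisfies: text in, entries out."""

    backend_id: str

    def extract(self, text: str) -> list[dict[str, str]]: ...


@dataclass
class ExtractionResult:
    """All entries extracted from one publication, with audit trail."""

    source_id: str
    entries: list[dict] = field(default_factory=list)
    backend_id: str = ""
    raw_response: str = ""

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "source_id": self.source_id,
                    "backend_id": self.backend_id,
                    "entries": self.entries,
                    "raw_response": self.raw_response,
                },
                indent=1,
                default=str,
            )
        )
        return path


class ExtractionError(RuntimeError):
    """Backend failure; the raw response is preserved for audit."""

    def __init__(self, message: str, raw_response: str = ""):
        super().__init__(message)
        self.raw_response = raw_response


# ---------------------------------------------------------------------------
# Rule-based reference backend
# ---------------------------------------------------------------------------

_AA = "".join(sorted(AMINO_ACIDS))

_SAMPLE_ANCHOR = re.compile(r"\bSample\s+(\d+)\s*:")
_SEQ = re.compile(rf"\b(?:dipeptide|tripeptide|peptide)\s+([{_AA}]{{2,3}})\b")
_TOPOLOGY = re.compile(r"\b(linear|cyclic)\b", re.IGNORECASE)
_NTERM = re.compile(r"N-terminal modification\s+([^,;.]+)", re.IGNORECASE)
_CTERM = re.compile(r"C-terminal modification\s+([^,;.]+)", re.IGNORECASE)
_SIDE = re.compile(r"side-chain modification\s+([^,;.]+)", re.IGNORECASE)
_CATEGORY = re.compile(r"\b(?:as|forming)\s+a\s+(peptide|conjugate|mixture)\s+system", re.IGNORECASE)
_PARTNER = re.compile(r"conjugate partner\s+([^,;.]+)", re.IGNORECASE)
_SOLVENT = re.compile(
    r"dissolved in\s+(?:a\s+)?([\w -]+?)(?:\s+containing\s+([^.]+?))?\s+at a",
    re.IGNORECASE,
)
_CONC = re.compile(
    r"concentration of\s+(\d+(?:\.\d+)?)\s*(mg/ml|mM|uM|µM)", re.IGNORECASE
)
_RATIO = re.compile(r"solvent ratio of\s+(\d+(?:\.\d+)?)", re.IGNORECASE)
_PH = re.compile(r"\bpH(?:\s+of)?\s+(\d+(?:\.\d+)?)")
_TEMP = re.compile(r"temperature of\s+(\d+(?:\.\d+)?)", re.IGNORECASE)
_THERMAL = re.compile(r"thermal process\s+(none|heating|cooling)", re.IGNORECASE)
_PHASE = re.compile(
    r"(?:assembled into|formed|forming|yielding)\s+(?:a\s+|an\s+)?([\w-]+?)s?\s+(?:phase|structure|network|morpholog)",
    re.IGNORECASE,
)
_NO_ASSEMBLY = re.compile(r"\bno (?:self-)?assembly\b", re.IGNORECASE)


def _first(pattern: re.Pattern, text: str, group: int = 1) -> str:
    m = pattern.search(text)
    return m.group(group).strip() if m else MISSING_TOKEN


class RuleBasedBackend:
    """Deterministic pattern-rule extractor used as the reference backend.

    Splits the text into per-sample segments anchored on ``Sample N:``
    mentions (falling back to one whole-text entry when a peptide is
    mentioned without anchors), then captures each field with a dedicated
    pattern.  Fields never found are reported as the missing marker rather
    than invented.
    """

    backend_id = "rule"

    def extract(self, text: str) -> list[dict[str, str]]:
        anchors = list(_SAMPLE_ANCHOR.finditer(text))
        if not anchors:
            if _SEQ.search(text):
                return [self._extract_entry(text)]
            return []
        # group every anchored segment by its sample number (a sample's
        # conditions and its observed phase typically sit in different
        # sections of the paper)
        segments: dict[int, list[str]] = {}
        for i, m in enumerate(anchors):
            end = anchors[i + 1].start() if i + 1 < len(anchors) else len(text)
            segments.setdefault(int(m.group(1)), []).append(text[m.start() : end])
        entries = []
        for num in sorted(segments):
            entry = self._extract_entry("\n".join(segments[num]))
            entry["sample"] = str(num)
            entries.append(entry)
        return entries

    def _extract_entry(self, segment: str) -> dict[str, str]:
        entry = {f: MISSING_TOKEN for f in ENTITY_FIELDS}
        entry["sequence"] = _first(_SEQ, segment)
        m = _TOPOLOGY.search(segment)
        if m:
            entry["topology"] = m.group(1).lower()
        entry["n_term_mod"] = _first(_NTERM, segment)
        entry["c_term_mod"] = _first(_CTERM, segment)
        entry["nonterm_mod"] = _first(_SIDE, segment)
        cat = _CATEGORY.search(segment)
        if cat:
            entry["system_category"] = cat.group(1).lower()
        entry["conjugate_partner"] = _first(_PARTNER, segment)
        sol = _SOLVENT.search(segment)
        if sol:
            entry["solvent"] = sol.group(1).strip()
            if sol.group(2):
                solutes = re.split(r",| and ", sol.group(2))
                entry["solutes"] = SOLUTE_DELIMITER.join(
                    s.strip() for s in solutes if s.strip()
                )
            else:
                entry["solutes"] = ""
        conc = _CONC.search(segment)
        if conc:
            entry["concentration"] = f"{conc.group(1)} {conc.group(2)}"
        entry["solvent_ratio"] = _first(_RATIO, segment)
        entry["ph"] = _first(_PH, segment)
        entry["temperature"] = _first(_TEMP, segment)
        therm = _THERMAL.search(segment)
        if therm:
            entry["thermal_process"] = therm.group(1).lower()
        if _NO_ASSEMBLY.search(segment):
            entry["phase"] = "no-assembly"
        else:
            entry["phase"] = _first(_PHASE, segment).lower() if _PHASE.search(segment) else MISSING_TOKEN
        return entry


#: Registry of extraction backends.
BACKENDS: dict[str, Callable[[], ExtractionBackend]] = {
    "rule": RuleBasedBackend,
}


def extract_records(
    text: str,
    backend: ExtractionBackend | str = "rule",
    source_id: str = "",
) -> ExtractionResult:
    """Run an extraction backend over preprocessed text.

    Returns one :class:`ExtractionResult` per publication, possibly holding
    several entries.  Text with no recognizable peptide mention yields an
    empty entry list, not an error; backend failures raise
    :class:`ExtractionError` with the raw response attached.
    """
    if isinstance(backend, str):
        try:
            backend = BACKENDS[backend]()
        except KeyError:
            raise ValueError(f"unknown backend {backend!r}; registered: {sorted(BACKENDS)}")
    try:
        entries = backend.extract(text)
    except ExtractionError:
        raise
    except Exception as exc:
        raise ExtractionError(f"backend {backend.backend_id!r} failed: {exc}") from exc
    if not isinstance(entries, list) or not all(isinstance(e, dict) for e in entries):
        raise ExtractionError(
            f"backend {backend.backend_id!r} returned unparseable output",
            raw_response=repr(entries),
        )
    return ExtractionResult(
        source_id=source_id,
        entries=entries,
        backend_id=backend.backend_id,
        raw_response=json.dumps(entries, default=str),
    )


# ---------------------------------------------------------------------------
# Coercion into the dataset schema
# ---------------------------------------------------------------------------

#: Spelling/synonym variants mapped onto canonical phase and category labels.
DEFAULT_ALIASES = {
    "fibre": "fiber",
    "nanofiber": "fiber",
    "nanofibre": "fiber",
    "fibril": "fiber",
    "nanotube": "tube",
    "microtube": "tube",
    "gel": "hydrogel",
    "nanosphere": "sphere",
    "microsphere": "sphere",
    "nanoparticle": "particle",
    "microparticle": "particle",
    "nanoribbon": "ribbon",
    "no assembly": "no-assembly",
    "noassembly": "no-assembly",
    "non-assembly": "no-assembly",
}


def _canonical(value: str, vocabulary: Sequence[str], aliases: dict[str, str]) -> Optional[str]:
    v = value.strip().lower()
    v = aliases.get(v, v)
    for cat in vocabulary:
        if v == cat.lower():
            return cat
    return None


def _coerce_numeric(value: str) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def coerce_fields(
    raw_entries: Sequence[dict],
    schema: VocabularySchema,
    aliases: Optional[dict[str, str]] = None,
) -> list[dict]:
    """Normalize raw backend strings into schema-conformant partial records.

    Coercion is total: a value that cannot be parsed or mapped into the
    schema becomes ``None`` (missing) and is logged, never an error.
    Concentrations with molar units are standardized to mg/ml using the
    extracted sequence's molecular weight.
    """
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    out = []
    for raw in raw_entries:
        entry: dict = {f: None for f in ENTITY_FIELDS if f != "solutes"}
        entry["solutes"] = ()

        def get(field: str) -> Optional[str]:
            v = raw.get(field)
            if v is None:
                return None
            v = str(v).strip()
            return None if not v or v.lower() == MISSING_TOKEN else v

        seq = get("sequence")
        if seq and len(seq) in (2, 3) and all(c in AMINO_ACIDS for c in seq.upper()):
            entry["sequence"] = seq.upper()

        for feat, vocab in (
            ("n_term_mod", schema.n_term_mod),
            ("c_term_mod", schema.c_term_mod),
            ("nonterm_mod", schema.nonterm_mod),
            ("system_category", schema.system_category),
            ("conjugate_partner", schema.conjugate_partner),
            ("thermal_process", schema.thermal_process),
            ("topology", schema.topology),
            ("solvent", schema.solvents),
        ):
            v = get(feat)
            if v is not None:
                mapped = _canonical(v, vocab, aliases)
                if mapped is None:
                    logger.info("unmappable %s value %r -> missing", feat, v)
                entry[feat] = mapped

        solutes_raw = raw.get("solutes")
        if solutes_raw not in (None, MISSING_TOKEN):
            mapped_solutes = []
            for s in str(solutes_raw).split(SOLUTE_DELIMITER):
                if not s.strip():
                    continue
                mapped = _canonical(s, schema.solutes, aliases)
                if mapped is None:
                    logger.info("unmappable solute %r -> dropped", s)
                else:
                    mapped_solutes.append(mapped)
            entry["solutes"] = tuple(mapped_solutes)

        conc = get("concentration")
        if conc is not None:
            try:
                value, unit = parse_quantity(conc)
                entry["concentration"] = concentration_to_mg_ml(
                    value, unit, entry["sequence"] or ""
                )
            except ValueError as exc:
                logger.info("unparseable concentration %r: %s", conc, exc)

        for feat in ("solvent_ratio", "ph", "temperature"):
            v = get(feat)
            if v is not None:
                entry[feat] = _coerce_numeric(v)

        phase = get("phase")
        if phase is not None:
            entry["phase"] = _canonical(phase, PHASES, aliases)
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# Fine-tuning export
# ---------------------------------------------------------------------------

ENTITY_PROMPT = (
    "Extract every experimental data entry from the following peptide "
    "self-assembly text. For each entry report: "
    + ", ".join(ENTITY_FIELDS)
    + ". Use 'nan' for values not stated.\n\n"
)


def export_finetune_pairs(
    records_by_source: dict[str, Sequence[PeptideRecord]],
    texts_by_source: dict[str, str],
    path: str | Path,
) -> Path:
    """Write prompt/completion pairs (JSON lines) for supervised fine-tuning.

    One pair per publication; the completion aggregates all of the paper's
    data entries so a model learns to emit multiple entries per document.
    """
    path = Path(path)
    with path.open("w") as fh:
        for source_id in sorted(records_by_source):
            if source_id not in texts_by_source:
                logger.warning("no document text for %s; skipped", source_id)
                continue
            completion = [
                {
                    k: (MISSING_TOKEN if v is None else v)
                    for k, v in r.to_row().items()
                    if k != "source_id"
                }
                for r in records_by_source[source_id]
            ]
            fh.write(
                json.dumps(
                    {
                        "prompt": ENTITY_PROMPT + texts_by_source[source_id],
                        "completion": json.dumps(completion),
                    }
                )
                + "\n"
            )
    return path
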