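"""Publication-text preprocessing for literature mining.

Pipeline: locate the experimental section by its heading, keep paragraphs
that mention a keyword from the mining vocabulary, drop formatting noise
(very short paragraphs and lines), prepend the abstract, and enforce a
token budget by trimming the body from both ends (introductions and
conclusions carry the least experimental detail, so the middle is kept).

Documents arrive as plain text; a PDF must be converted externally and the
converter is injectable (``load_document(converter=...)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

# Headings that open an experimental section, as regex templates.  Matching
# is case-insensitive, tolerates numbering prefixes ("2. Materials and
# Methods") and the singular/plural "(s)" variants.
START_HEADINGS = (
    r"materials?\s+and\s+methods?",
    r"methods?\s+and\s+materials?",
    r"experimental\s+sections?",
    r"experimental\s+details?",
    r"materials?",
    r"methods?",
)

# Headings of the section immediately after the experimental part.
END_HEADINGS = (
    r"results?\s+and\s+discussions?",
    r"results?\s+and\s+conclusions?",
    r"results?",
    r"discussions?",
    r"conclusions?",
    r"literature\s+cited",
    r"acknowledge?ments?",
    r"references?",
    r"associated\s+contents?",
    r"author\s+information",
    r"conflicts?\s+of\s+interests?",
)

# Reconstructable core of the mining keyword vocabulary: the phase names
# plus the experimental-condition terms.  User-extensible via PipelineConfig.
DEFAULT_KEYWORDS = (
    "fiber",
    "hydrogel",
    "sphere",
    "tube",
    "particle",
    "ribbon",
    "vesicle",
    "assembl",  # matches self-assembly / assembled / assemblies
    "concentration",
    "pH",
    "temperature",
    "solvent",
    "peptide",
)


def whitespace_tokenize(text: str) -> list[str]:
    """Deterministic fallback tokenizer: whitespace-delimited tokens."""
    return text.split()


#: Registry of tokenizers by id; all deterministic.
TOKENIZERS: dict[str, Callable[[str], list[str]]] = {
    "whitespace": whitespace_tokenize,
}


@dataclass
class PipelineConfig:
    """Knobs of the preprocessing pipeline with the protocol defaults."""

    start_headings: tuple[str, ...] = START_HEADINGS
    end_headings: tuple[str, ...] = END_HEADINGS
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    min_paragraph_chars: int = 100
    min_line_chars: int = 9
    token_limit: int = 4096
    tokenizer_id: str = "whitespace"

    def __post_init__(self):
        if not self.start_headings or not self.end_headings:
            raise ValueError("heading lists must be nonempty")
        if min(self.min_paragraph_chars, self.min_line_chars, self.token_limit) <= 0:
            raise ValueError("limits must be positive")

    @property
    def tokenizer(self) -> Callable[[str], list[str]]:
        return TOKENIZERS[self.tokenizer_id]


@dataclass
class DocumentText:
    """A publication's text: abstract, body, and paragraph view."""

    body: str
    abstract: str = ""
    provenance: str = ""

    @property
    def paragraphs(self) -> list[str]:
        return split_paragraphs(self.body)


_PARAGRAPH_SPLIT = re.compile(r"\n\s*\n")


def split_paragraphs(text: str) -> list[str]:
    """Split on one-or-more blank lines; drops empty fragments."""
    return [p.strip("\n") for p in _PARAGRAPH_SPLIT.split(text) if p.strip()]


def _heading_pattern(templates: Sequence[str]) -> re.Pattern:
    # a heading sits on its own line, optionally numbered, optionally ending
    # with a colon or period
    alts = "|".join(f"(?:{t})" for t in templates)
    return re.compile(
        rf"^\s*(?:\d+(?:\.\d+)*[.)]?\s+)?({alts})\s*[:.]?\s*$",
        re.IGNORECASE | re.MULTILINE,
    )


def segment_experimental(doc: DocumentText, cfg: PipelineConfig) -> str:
    """Extract the experimental section between its heading and the next section.

    Falls back gracefully: with no recognized start heading the complete
    body is kept; with no end heading after the start, everything from the
    start heading to the end of the document is included.
    """
    body = doc.body
    start_m = _heading_pattern(cfg.start_headings).search(body)
    if start_m is None:
        return body
    start = start_m.end()
    end_m = _heading_pattern(cfg.end_headings).search(body, start)
    return body[start : end_m.start()] if end_m else body[start:]


def select_paragraphs(text: str, cfg: PipelineConfig) -> list[str]:
    """Keep keyword-bearing paragraphs and strip formatting noise.

    A paragraph survives iff it contains at least one keyword
    (case-insensitive substring match) and is at least
    ``min_paragraph_chars`` long; within survivors, lines shorter than
    ``min_line_chars`` (typical PDF-extraction debris) are removed.
    """
    if not cfg.keywords:
        raise ValueError("keyword vocabulary must be nonempty")
    lowered = [k.lower() for k in cfg.keywords]
    kept = []
    for para in split_paragraphs(text):
        if len(para) < cfg.min_paragraph_chars:
            continue
        hay = para.lower()
        if not any(k in hay for k in lowered):
            continue
        lines = [
            ln for ln in para.splitlines() if len(ln.strip()) >= cfg.min_line_chars
        ]
        if lines:
            kept.append("\n".join(lines))
    return kept


@dataclass
class AssembledInput:
    """Final model input text with its token accounting."""

    text: str
    token_count: int
    truncated: bool
    tokenizer_id: str
    warnings: list[str] = field(default_factory=list)


def assemble_input(
    abstract: str, paragraphs: Sequence[str], cfg: PipelineConfig
) -> AssembledInput:
    """Prepend the abstract and enforce the token budget.

    If the combined text exceeds ``token_limit``, the body is trimmed from
    both ends — keeping its middle — until it fits; the abstract is
    protected (only truncated, tail-first with a warning, if it alone
    exceeds the budget).
    """
    tok = cfg.tokenizer
    warnings: list[str] = []
    abstract = abstract.strip()
    a_tokens = tok(abstract) if abstract else []
    if len(a_tokens) > cfg.token_limit:
        warnings.append(
            f"abstract alone ({len(a_tokens)} tokens) exceeds the "
            f"{cfg.token_limit}-token limit; tail-truncated"
        )
        abstract = " ".join(a_tokens[: cfg.token_limit])
        return AssembledInput(
            text=abstract,
            token_count=cfg.token_limit,
            truncated=True,
            tokenizer_id=cfg.tokenizer_id,
            warnings=warnings,
        )

    body = "\n\n".join(paragraphs).strip()
    b_tokens = tok(body) if body else []
    budget = cfg.token_limit - len(a_tokens)
    truncated = False
    if len(b_tokens) > budget:
        truncated = True
        cut = len(b_tokens) - budget
        cut_front = (cut + 1) // 2
        cut_back = cut // 2
        b_tokens = b_tokens[cut_front : len(b_tokens) - cut_back]
        body = " ".join(b_tokens)

    text = f"{abstract}\n\n{body}".strip() if abstract else body
    return AssembledInput(
        text=text,
        token_count=len(a_tokens) + len(b_tokens),
        truncated=truncated,
        tokenizer_id=cfg.tokenizer_id,
        warnings=warnings,
    )


def preprocess_document(
    doc: DocumentText, cfg: Optional[PipelineConfig] = None
) -> tuple[AssembledInput, dict]:
    """Run the full pipeline; returns the model input plus a manifest."""
    cfg = cfg or PipelineConfig()
    section = segment_experimental(doc, cfg)
    total = split_paragraphs(section)
    kept = select_paragraphs(section, cfg)
    assembled = assemble_input(doc.abstract, kept, cfg)
    manifest = {
        "provenance": doc.provenance,
        "section_chars": len(section),
        "paragraphs_total": len(total),
        "paragraphs_kept": len(kept),
        "token_count": assembled.token_count,
        "token_limit": cfg.token_limit,
        "truncated": assembled.truncated,
        "tokenizer_id": assembled.tokenizer_id,
        "warnings": assembled.warnings,
    }
    return assembled, manifest


_ABSTRACT_HEADING = re.compile(r"^\s*abstract\s*[:.]?\s*$", re.IGNORECASE | re.MULTILINE)


def load_document(
    path: str | Path,
    converter: Optional[Callable[[Path], str]] = None,
) -> DocumentText:
    """Load a publication document from plain text (or via a PDF converter).

    If a line reading "Abstract" is present, the following paragraph is
    taken as the abstract; the body is the full text either way.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdf":
        if converter is None:
            raise ValueError(
                "PDF input requires a converter callable (PDF -> text); "
                "plain-text files are read directly"
            )
        text = converter(path)
    else:
        text = path.read_text()
    abstract = ""
    m = _ABSTRACT_HEADING.search(text)
    if m:
        following = split_paragraphs(text[m.end() :])
        if following:
            abstract = following[0]
    return DocumentText(body=text, abstract=abstract, provenance=path.name)
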