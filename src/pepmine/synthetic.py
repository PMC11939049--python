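"""Seeded generators for synthetic datasets and publication documents.

The tabular generator emulates the statistical shape of the curated
experimental dataset: di/tripeptide sequences over the 20 amino acids, nine
categorical and four numerical features, eight phase classes with strong
imbalance (non-assembly and hydrogel dominant), and multiple records per
source publication.  The label mechanism is controllable:

* ``rule`` — the phase is a stated deterministic function of interpretable
  feature clauses (sequence motif, solvent, concentration bin, ...), so
  classifiers should learn it almost perfectly and attribution analyses
  have known ground truth;
* ``noisy`` — the rule plus label flips with probability ``epsilon``;
* ``shuffled`` — rule labels randomly permuted across records, destroying
  all signal (a classifier should fall to the 1/8 chance level).

The document generator renders one publication's records into a templated
paper — abstract, Materials and Methods stating conditions, Results and
Discussion stating phases, keyword-free distractor paragraphs, and
sub-threshold noise lines — with the input records as exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .dataset_model import PHASES, PeptideRecord
from .litmine_text import DEFAULT_KEYWORDS, DocumentText

#: Default class probabilities, skewed like the curated dataset (non-assembly
#: and hydrogel dominate; ribbon and vesicle are rare).
DEFAULT_CLASS_PROBS = {
    "no-assembly": 0.30,
    "hydrogel": 0.24,
    "fiber": 0.16,
    "tube": 0.08,
    "sphere": 0.08,
    "particle": 0.06,
    "ribbon": 0.04,
    "vesicle": 0.04,
}

N_TERM_MODS = ("none", "Fmoc", "Boc", "acetyl")
C_TERM_MODS = ("none", "amide", "methyl ester")
NONTERM_MODS = ("none", "phosphate", "methyl")
PARTNERS = ("PEG", "naphthalene", "cholesterol")
SOLVENTS = ("water", "DMSO", "ethanol", "methanol")
SOLUTES = ("NaOH", "HCl", "NaCl")

PHASE_RULE_DESCRIPTION = """\
Deterministic phase rule (first matching clause wins):
 1. concentration < 1 mg/ml                          -> no-assembly
 2. FF motif in sequence, water, conc >= 5 mg/ml     -> fiber
 3. FF motif in sequence, water                      -> hydrogel
 4. cyclic topology                                  -> tube
 5. DMSO solvent, pH < 5                             -> sphere
 6. DMSO solvent                                     -> particle
 7. Fmoc N-terminal modification                     -> ribbon
 8. otherwise                                        -> vesicle
"""


def phase_rule(r: PeptideRecord) -> str:
    """The stated deterministic feature->phase mapping (see module docs)."""
    conc = r.concentration if r.concentration is not None else 0.0
    if conc < 1.0:
        return "no-assembly"
    if "FF" in r.sequence and r.solvent == "water":
        return "fiber" if conc >= 5.0 else "hydrogel"
    if r.topology == "cyclic":
        return "tube"
    if r.solvent == "DMSO":
        return "sphere" if (r.ph is not None and r.ph < 5.0) else "particle"
    if r.n_term_mod == "Fmoc":
        return "ribbon"
    return "vesicle"


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the tabular generator."""

    n_records: int = 1000
    n_publications: int = 75
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    label_mechanism: Literal["rule", "noisy", "shuffled"] = "rule"
    epsilon: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_publications > self.n_records:
            raise ValueError(
                f"{self.n_publications} publications cannot each hold a record "
                f"with only {self.n_records} records"
            )
        probs = [self.class_probs.get(p, 0.0) for p in PHASES]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


def _random_sequence(rng: np.random.Generator, with_ff: Optional[bool] = None) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    while True:
        length = int(rng.choice([2, 3], p=[0.55, 0.45]))
        seq = "".join(rng.choice(list(aas), size=length))
        if with_ff is True:
            if length == 2:
                seq = "FF"
            else:
                seq = "FF" + seq[2] if rng.random() < 0.5 else seq[0] + "FF"
        if with_ff is False and "FF" in seq:
            continue
        return seq


def _base_fields(rng: np.random.Generator) -> dict:
    """Random draw of fields before phase-specific adjustment."""
    if rng.random() < 0.2:
        category, partner = "conjugate", str(rng.choice(PARTNERS))
    elif rng.random() < 0.12:
        category, partner = "mixture", "none"
    else:
        category, partner = "peptide", "none"
    solutes = tuple(rng.choice(SOLUTES, size=1)) if rng.random() < 0.35 else ()
    return {
        "n_term_mod": str(rng.choice(N_TERM_MODS)),
        "c_term_mod": str(rng.choice(C_TERM_MODS)),
        "nonterm_mod": str(rng.choice(NONTERM_MODS)),
        "system_category": category,
        "conjugate_partner": partner,
        "thermal_process": str(rng.choice(("none", "heating", "cooling"), p=(0.7, 0.2, 0.1))),
        "topology": "linear",
        "solvent": str(rng.choice(SOLVENTS)),
        "solutes": solutes,
        "solvent_ratio": float(np.round(rng.uniform(0.5, 1.0), 2)),
        "concentration": float(np.round(rng.uniform(1.0, 10.0), 2)),
        "ph": float(np.round(rng.uniform(2.0, 12.0), 1)),
        "temperature": float(np.round(rng.uniform(15.0, 60.0), 1)),
    }


def _fields_for_phase(phase: str, rng: np.random.Generator) -> dict:
    """Constructive sampling: fields guaranteed to satisfy ``phase_rule``."""
    f = _base_fields(rng)
    f["sequence"] = _random_sequence(rng)
    if phase == "no-assembly":
        f["concentration"] = float(np.round(rng.uniform(0.1, 0.9), 2))
        return f
    # every other phase requires conc >= 1 (clause 1 must not fire)
    if phase == "fiber":
        f["sequence"] = _random_sequence(rng, with_ff=True)
        f["solvent"] = "water"
        f["concentration"] = float(np.round(rng.uniform(5.0, 10.0), 2))
    elif phase == "hydrogel":
        f["sequence"] = _random_sequence(rng, with_ff=True)
        f["solvent"] = "water"
        f["concentration"] = float(np.round(rng.uniform(1.0, 4.9), 2))
    elif phase == "tube":
        f["sequence"] = _random_sequence(rng, with_ff=False)
        f["topology"] = "cyclic"
    elif phase == "sphere":
        f["sequence"] = _random_sequence(rng, with_ff=False)
        f["solvent"] = "DMSO"
        f["ph"] = float(np.round(rng.uniform(2.0, 4.9), 1))
    elif phase == "particle":
        f["sequence"] = _random_sequence(rng, with_ff=False)
        f["solvent"] = "DMSO"
        f["ph"] = float(np.round(rng.uniform(5.0, 12.0), 1))
    elif phase == "ribbon":
        f["sequence"] = _random_sequence(rng, with_ff=False)
        f["n_term_mod"] = "Fmoc"
        f["solvent"] = str(rng.choice(("ethanol", "methanol")))
    elif phase == "vesicle":
        f["sequence"] = _random_sequence(rng, with_ff=False)
        f["n_term_mod"] = str(rng.choice(("none", "Boc", "acetyl")))
        f["solvent"] = str(rng.choice(("ethanol", "methanol")))
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return f


def synth_dataset(spec: SyntheticSpec) -> tuple[list[PeptideRecord], str]:
    """Generate a synthetic record set plus a description of the labelling rule.

    Class frequencies follow ``spec.class_probs`` (multinomial draw); under
    the ``rule`` mechanism the phase label is exactly ``phase_rule`` applied
    to the features.  Records are grouped into publications, each holding at
    least one record.  Fixed seed implies byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.class_probs.get(p, 0.0) for p in PHASES])
    phases = rng.choice(PHASES, size=spec.n_records, p=probs)

    pubs = [f"synthPUB-{i:03d}" for i in range(spec.n_publications)]
    assignment = list(range(spec.n_publications)) + list(
        rng.integers(0, spec.n_publications, size=spec.n_records - spec.n_publications)
    )
    rng.shuffle(assignment)

    records = []
    for i, phase in enumerate(phases):
        fields = _fields_for_phase(str(phase), rng)
        if spec.missing_rate > 0:
            for feat in ("ph", "temperature"):
                if rng.random() < spec.missing_rate:
                    fields[feat] = None
        label = phase_rule(PeptideRecord(**fields, phase="no-assembly"))
        records.append(
            PeptideRecord(**fields, phase=label, source_id=pubs[assignment[i]])
        )

    if spec.label_mechanism == "noisy" and spec.epsilon > 0:
        records = [
            r.model_copy(
                update={
                    "phase": str(rng.choice([p for p in PHASES if p != r.phase]))
                }
            )
            if rng.random() < spec.epsilon
            else r
            for r in records
        ]
    elif spec.label_mechanism == "shuffled":
        labels = [r.phase for r in records]
        perm = rng.permutation(len(labels))
        records = [
            r.model_copy(update={"phase": labels[perm[i]]})
            for i, r in enumerate(records)
        ]

    return records, PHASE_RULE_DESCRIPTION


# ---------------------------------------------------------------------------
# Document generator
# ---------------------------------------------------------------------------

# Distractor prose containing no mining keyword (asserted at module import).
_DISTRACTOR_PARAGRAPHS = (
    "The glassware was rinsed three times with deionized liquid and dried "
    "overnight in a clean oven before use. All containers were covered "
    "during storage to avoid dust, and labels were renewed weekly.",
    "Data were archived on the laboratory server, and instrument logbooks "
    "were reviewed at the end of every month by the designated custodian "
    "in accordance with internal record-keeping rules.",
)

for _p in _DISTRACTOR_PARAGRAPHS:  # construction guarantee for the filters
    assert not any(k.lower() in _p.lower() for k in DEFAULT_KEYWORDS), _p

_PHASE_SENTENCES = {
    "no-assembly": "no assembly was observed and the solution remained clear",
    "hydrogel": "the system self-assembled into a hydrogel phase",
    "fiber": "the system self-assembled into a fiber phase",
    "tube": "the system self-assembled into a tube phase",
    "sphere": "the system self-assembled into a sphere phase",
    "particle": "the system self-assembled into a particle phase",
    "ribbon": "the system self-assembled into a ribbon phase",
    "vesicle": "the system self-assembled into a vesicle phase",
}

# noisy phase wording still coercible through the alias table
_NOISY_PHASE_WORDS = {
    "fiber": "nanofiber",
    "tube": "nanotube",
    "hydrogel": "gel",
    "sphere": "nanosphere",
    "particle": "nanoparticle",
    "ribbon": "nanoribbon",
    "vesicle": "vesicle",
}


def _fmt(v: Optional[float]) -> str:
    return "an unreported value" if v is None else f"{v:g}"


def _methods_paragraph(i: int, r: PeptideRecord) -> str:
    kind = "dipeptide" if len(r.sequence) == 2 else "tripeptide"
    solutes = (
        " containing " + " and ".join(r.solutes) if r.solutes else ""
    )
    conc = (
        f"a concentration of {r.concentration:g} mg/ml"
        if r.concentration is not None
        else "an unstated concentration"
    )
    ratio = (
        f"a solvent ratio of {r.solvent_ratio:g}"
        if r.solvent_ratio is not None
        else "an unstated solvent ratio"
    )
    ph = f"a pH of {r.ph:g}" if r.ph is not None else "an unadjusted acidity"
    temp = (
        f"a temperature of {r.temperature:g} degrees Celsius"
        if r.temperature is not None
        else "ambient warmth"
    )
    return (
        f"Sample {i}: the {r.topology} {kind} {r.sequence}, with N-terminal "
        f"modification {r.n_term_mod}, C-terminal modification {r.c_term_mod}, "
        f"and side-chain modification {r.nonterm_mod}, was studied as a "
        f"{r.system_category} system with conjugate partner "
        f"{r.conjugate_partner}. The peptide was dissolved in {r.solvent}"
        f"{solutes} at {conc}, with {ratio} and {ph}. The sample was kept at "
        f"{temp} with thermal process {r.thermal_process}."
    )


def _results_paragraph(i: int, r: PeptideRecord, noisy: bool) -> str:
    sentence = _PHASE_SENTENCES[r.phase]
    if noisy and r.phase in _NOISY_PHASE_WORDS:
        sentence = (
            f"the system self-assembled into a {_NOISY_PHASE_WORDS[r.phase]} phase"
        )
    return (
        f"Sample {i}: upon incubation under the stated conditions, electron "
        f"microscopy of the peptide system revealed that {sentence}.\n"
        f"Fig. {i}"
    )


def synth_document(
    records: Sequence[PeptideRecord],
    template_id: Literal["sectioned", "headingless"] = "headingless",
    noise_level: float = 0.0,
    seed: int = 0,
) -> tuple[DocumentText, list[PeptideRecord]]:
    """Render one publication's records into a templated paper.

    The document carries an abstract, a Materials and Methods section
    stating all conditions (one sample paragraph per record), a Results and
    Discussion section stating the phases, keyword-free distractor
    paragraphs, and sub-threshold noise lines.  The returned ground truth
    is exactly the input records.

    ``sectioned`` uses explicit section headings (so preprocessing cuts at
    "Results and Discussion" and phase statements are lost — the
    sparse-information challenge of real papers); ``headingless`` has no
    recognized headings, so the complete text is kept and phases are
    recoverable.  ``noise_level > 0`` swaps phase wording for synonym
    variants and randomly withholds the solvent-ratio clause.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    sources = {r.source_id for r in records}
    if len(sources) != 1:
        raise ValueError(f"records must share one source_id (got {sources})")
    rng = np.random.default_rng(seed)

    abstract = (
        "Short peptides are versatile building blocks that self-assemble "
        "into diverse nanostructures. In this synthetic study we examine "
        f"{len(records)} peptide systems under controlled solution "
        "conditions and report the observed phases, from hydrogels and "
        "fibers to the absence of assembly."
    )

    methods = []
    for i, r in enumerate(records, start=1):
        para = _methods_paragraph(i, r)
        if (
            noise_level > 0
            and r.solvent_ratio is not None
            and rng.random() < noise_level
        ):
            para = para.replace(
                f", with a solvent ratio of {r.solvent_ratio:g}", ","
            ).replace(
                f"with a solvent ratio of {r.solvent_ratio:g} and", "with"
            )
        methods.append(para)
    results = [
        _results_paragraph(
            i, r, noisy=noise_level > 0 and rng.random() < noise_level
        )
        for i, r in enumerate(records, start=1)
    ]

    noise_lines = "\n".join(["Tab. 1", "a.u.", "p. 12"])

    if template_id == "sectioned":
        parts = [
            "A synthetic study of short-peptide assembly",
            "Abstract",
            abstract,
            "Introduction",
            "Prior reports have described many routes to ordered aggregates; "
            "this synthetic document exists to exercise a mining pipeline and "
            "cites no real work.",
            "Materials and Methods",
            _DISTRACTOR_PARAGRAPHS[0],
            *methods,
            noise_lines,
            "Results and Discussion",
            *results,
            _DISTRACTOR_PARAGRAPHS[1],
            "References",
            "1. A synthetic citation.",
        ]
    elif template_id == "headingless":
        parts = [
            "A synthetic study of short-peptide assembly",
            "Abstract",
            abstract,
            _DISTRACTOR_PARAGRAPHS[0],
            *methods,
            noise_lines,
            *results,
            _DISTRACTOR_PARAGRAPHS[1],
        ]
    else:
        raise ValueError(f"unknown template_id {template_id!r}")

    doc = DocumentText(
        body="\n\n".join(parts),
        abstract=abstract,
        provenance=f"{records[0].source_id}.txt",
    )
    return doc, records
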