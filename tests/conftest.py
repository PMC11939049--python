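import pytest
from hypothesis import HealthCheck, settings

from pepmine.dataset_model import PHASES, PeptideRecord, build_vocabularies
from pepmine.encoding import encode_records
from pepmine.synthetic import SyntheticSpec, synth_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_records():
    """Four hand-written records with known categories and numerics."""
    return [
        PeptideRecord(
            sequence="FF", phase="hydrogel", concentration=1.0, ph=7.0,
            temperature=25.0, solvent="water", solutes="NaOH", source_id="p1",
        ),
        PeptideRecord(
            sequence="FF", phase="fiber", concentration=5.0, ph=3.0,
            temperature=40.0, solvent="water", source_id="p1",
        ),
        PeptideRecord(
            sequence="GHK", phase="no-assembly", concentration=10.0, ph=11.0,
            temperature=25.0, solvent="DMSO", n_term_mod="Fmoc", source_id="p2",
        ),
        PeptideRecord(
            sequence="LVF", phase="vesicle", concentration=2.5, ph=7.0,
            temperature=60.0, solvent="ethanol", topology="cyclic",
            system_category="conjugate", conjugate_partner="PEG", source_id="p2",
        ),
    ]


@pytest.fixture(scope="session")
def rule_dataset():
    """1000 records labelled by the deterministic phase rule, 75 publications."""
    records, rule = synth_dataset(
        SyntheticSpec(n_records=1000, n_publications=75, seed=11)
    )
    return records


@pytest.fixture(scope="session")
def rule_schema(rule_dataset):
    return build_vocabularies(rule_dataset)


@pytest.fixture(scope="session")
def rule_encoded(rule_dataset, rule_schema):
    matrix, group_map = encode_records(rule_dataset, rule_schema)
    return matrix, group_map


@pytest.fixture(scope="session")
def uniform_shuffled_dataset():
    """Label-shuffled records with uniform class prior (chance level 1/8)."""
    records, _ = synth_dataset(
        SyntheticSpec(
            n_records=1000,
            n_publications=75,
            seed=13,
            label_mechanism="shuffled",
            class_probs={p: 1 / len(PHASES) for p in PHASES},
        )
    )
    return records
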