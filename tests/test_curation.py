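"""Curation rules: range expansion, critical-value bracketing, standardization,
and min-max normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pepmine.curation import (
    CriticalTransition,
    RangeSpec,
    bracket_critical,
    concentration_to_mg_ml,
    denormalize,
    expand_range,
    molecular_weight,
    normalize_features,
    parse_quantity,
    standardize_record,
)
from pepmine.dataset_model import PeptideRecord, build_vocabularies

# Independent oracle: average molecular weights of the free amino acids;
# peptide MW = sum of free-AA weights minus one water per peptide bond.
FREE_AA_MW = {"F": 165.19, "G": 75.07, "A": 89.09, "L": 131.17, "K": 146.19}
WATER = 18.02


def oracle_mw(seq):
    return sum(FREE_AA_MW[c] for c in seq) - (len(seq) - 1) * WATER


@pytest.fixture
def template():
    return PeptideRecord(sequence="FF", phase="hydrogel", concentration=2.0)


class TestExpandRange:
    def test_unit_spacing(self, template):
        out = expand_range(RangeSpec("concentration", 1.0, 6.0), template)
        assert [r.concentration for r in out] == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]

    def test_fractional_spacing(self, template):
        out = expand_range(RangeSpec("solvent_ratio", 0.0, 1.0), template)
        assert np.allclose([r.solvent_ratio for r in out], [0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_always_six_entries_other_fields_copied(self, template):
        out = expand_range(RangeSpec("temperature", 20.0, 80.0), template)
        assert len(out) == 6
        assert all(r.sequence == "FF" and r.phase == "hydrogel" for r in out)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            RangeSpec("concentration", 6.0, 1.0)

    @given(lo=st.floats(0.1, 5.0), width=st.floats(0.5, 10.0))
    def test_reversal_symmetry(self, lo, width):
        """Values from [lo, hi] equal the reverse of values from swapping ends."""
        template = PeptideRecord(sequence="FF", phase="hydrogel")
        fwd = expand_range(RangeSpec("concentration", lo, lo + width), template)
        vals = [r.concentration for r in fwd]
        assert np.allclose(vals, np.linspace(lo, lo + width, 6))
        assert np.allclose(vals, sorted(vals))


class TestBracketCritical:
    def test_example_c10(self, template):
        t = CriticalTransition("concentration", 10.0, "no-assembly", "hydrogel")
        out = bracket_critical(t, template)
        assert [(r.concentration, r.phase) for r in out] == [
            (8.0, "no-assembly"),
            (9.0, "no-assembly"),
            (11.0, "hydrogel"),
            (12.0, "hydrogel"),
        ]

    def test_unit_critical(self, template):
        t = CriticalTransition("concentration", 1.0, "no-assembly", "fiber")
        vals = [r.concentration for r in bracket_critical(t, template)]
        assert np.allclose(vals, [0.8, 0.9, 1.1, 1.2])

    def test_counts(self, template):
        t = CriticalTransition("ph", 4.0, "sphere", "particle")
        out = bracket_critical(t, template)
        assert len(out) == 4
        assert sum(r.phase == "sphere" for r in out) == 2
        assert sum(r.phase == "particle" for r in out) == 2

    @given(c=st.floats(0.5, 8.0))
    def test_homogeneity_in_critical_value(self, c):
        """Bracket values scale linearly with the critical value."""
        template = PeptideRecord(sequence="FF", phase="hydrogel")
        t = CriticalTransition("concentration", c, "no-assembly", "hydrogel")
        vals = np.array([r.concentration for r in bracket_critical(t, template)])
        assert np.allclose(vals / c, [0.8, 0.9, 1.1, 1.2])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CriticalTransition("concentration", -1.0, "no-assembly", "fiber")
        with pytest.raises(ValueError):
            CriticalTransition("concentration", 1.0, "fiber", "fiber")


class TestStandardize:
    def test_molecular_weight_against_oracle(self):
        for seq in ("FF", "GG", "FGL", "KLF"):
            assert molecular_weight(seq) == pytest.approx(oracle_mw(seq), rel=1e-3)

    def test_10mM_ff(self, template):
        # oracle: 10 mmol/l x 312.36 g/mol = 3123.6 mg/l = 3.1236 mg/ml
        out = standardize_record(template, "10 mM")
        assert out.concentration == pytest.approx(10 * oracle_mw("FF") / 1000, rel=1e-3)
        assert out.concentration == pytest.approx(3.1236, rel=1e-3)

    def test_micromolar(self, template):
        out = standardize_record(template, "500 uM")
        assert out.concentration == pytest.approx(0.5 * oracle_mw("FF") / 1000, rel=1e-3)

    def test_mg_ml_identity(self, template):
        assert standardize_record(template, "7.5 mg/ml").concentration == 7.5

    def test_missing_temperature_becomes_room_temperature(self):
        r = PeptideRecord(sequence="FF", phase="fiber")
        assert r.temperature is None
        assert standardize_record(r).temperature == 25.0

    def test_present_temperature_untouched(self):
        r = PeptideRecord(sequence="FF", phase="fiber", temperature=60.0)
        assert standardize_record(r).temperature == 60.0

    def test_default_ph_resolver_pure_water_only(self):
        water = PeptideRecord(sequence="FF", phase="fiber", solvent="water")
        assert standardize_record(water).ph == 7.0
        salty = PeptideRecord(sequence="FF", phase="fiber", solvent="water", solutes="NaCl")
        assert standardize_record(salty).ph is None
        organic = PeptideRecord(sequence="FF", phase="fiber", solvent="methanol")
        assert standardize_record(organic).ph is None

    def test_unknown_unit_errors(self, template):
        with pytest.raises(ValueError, match="unit"):
            standardize_record(template, "3 parsec")

    def test_parse_quantity(self):
        assert parse_quantity("2 mM") == (2.0, "mM")
        assert parse_quantity("10mg/ml") == (10.0, "mg/ml")

    def test_weight_percent_uses_density(self):
        assert concentration_to_mg_ml(1.0, "wt%", "FF") == pytest.approx(10.0)


class TestNormalize:
    def test_endpoints_and_midpoint(self, toy_records):
        schema = build_vocabularies(toy_records)
        lo, hi = schema.numeric_ranges["concentration"]
        mid_record = toy_records[0].model_copy(update={"concentration": (lo + hi) / 2})
        frame = normalize_features([mid_record] + toy_records, schema)
        concs = frame["concentration"].to_numpy()
        assert concs[0] == pytest.approx(0.5)
        assert concs.min() == pytest.approx(0.0) and concs.max() == pytest.approx(1.0)

    def test_missing_propagates(self):
        records = [
            PeptideRecord(sequence="FF", phase="fiber", concentration=1.0, ph=None),
            PeptideRecord(sequence="FF", phase="fiber", concentration=3.0, ph=7.0),
            PeptideRecord(sequence="GG", phase="fiber", concentration=5.0, ph=9.0),
        ]
        frame = normalize_features(records, build_vocabularies(records))
        assert np.isnan(frame["ph"].iloc[0])
        assert not frame["concentration"].isna().any()

    def test_degenerate_spread_warns_and_maps_to_zero(self):
        records = [
            PeptideRecord(sequence="FF", phase="fiber", concentration=2.0, ph=5.0),
            PeptideRecord(sequence="GG", phase="fiber", concentration=2.0, ph=9.0),
        ]
        with pytest.warns(UserWarning, match="zero spread"):
            frame = normalize_features(records, build_vocabularies(records))
        assert (frame["concentration"] == 0.0).all()

    @given(
        values=st.lists(st.floats(0.1, 99.0), min_size=3, max_size=10, unique=True)
    )
    def test_monotone_and_invertible(self, values):
        """Normalization preserves order; denormalization recovers raw values."""
        records = [
            PeptideRecord(sequence="FF", phase="fiber", concentration=v) for v in values
        ]
        schema = build_vocabularies(records)
        frame = normalize_features(records, schema)
        normed = frame["concentration"].to_numpy()
        assert (np.diff(normed[np.argsort(values)]) >= 0).all()
        recovered = denormalize(frame, schema)["concentration"].to_numpy()
        assert np.allclose(recovered, values, atol=1e-9)
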