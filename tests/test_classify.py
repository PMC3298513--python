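import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from waspfam.classify import (Architecture, CompletenessPolicy,
                              FamilyAssignment, assess_completeness, classify,
                              flag_pseudogene, resolve_architecture)
from waspfam.records import DomainCall, ProteinRecord

KIND_LENGTHS = {
    "WH1": 110, "WHD": 130, "WAHD": 140, "WMD": 260, "IMD": 180,
    "WAID": 30, "CRIB": 14, "B": 15, "PPR": 25, "SER": 20,
    "CHG": 600, "CC": 60, "WH2": 18, "C": 14, "A": 20,
    "WAM1": 20, "WAM2": 25, "WAM3": 15, "WAM4": 60,
    "WASHM1": 20, "WASHM2": 20,
}


def arch_from_string(kinds, gap=30, record_id="rec", tail=5):
    """Build a resolved Architecture by laying out kinds left to right."""
    calls = []
    pos = 10
    for kind in kinds:
        length = KIND_LENGTHS[kind]
        calls.append(DomainCall(record_id, kind, pos, pos + length - 1,
                                100.0 if kind in ("WH1", "WHD", "WAHD",
                                                  "WMD", "IMD", "WAID") else 5.0))
        pos += length + gap
    total = pos - gap + tail
    record = ProteinRecord(record_id, "A" * total)
    return resolve_architecture(record, calls), record


RULE_TABLE = [
    (("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "C", "A"), "WASP", "canonical"),
    (("WH1", "B", "WAID", "PPR", "WH2", "C", "A"), "WASP", "canonical"),
    (("WHD", "B", "PPR", "WH2", "C", "A"), "WAVE", "canonical"),
    (("WHD", "B", "WAM1", "WAM2", "WH2", "C", "A"), "WAVE", "canonical"),
    (("WAHD", "PPR", "WH2", "C", "A", "WH2", "C", "A"), "WASH", "tandem-VCA"),
    (("WAHD", "PPR", "WH2", "C", "A"), "WASH", "canonical"),
    (("WAHD", "PPR", "C", "A"), "WASH", "no-WH2"),
    (("WMD", "PPR", "WH2", "C", "A"), "WHAMM", "canonical"),
    (("IMD", "WAID", "PPR", "WH2", "C", "A"), "WAML", "canonical"),
    (("IMD", "WAID"), "WAML", "WAML-short"),
    (("B", "CRIB", "WAID", "PPR", "WH2", "C", "A"), "WAWH", "WAWH-I"),
    (("CRIB", "WAID", "CHG", "PPR", "WH2", "C", "A"), "WAWH", "WAWH-III"),
    (("WH1", "CRIB", "WAID"), "WASP", "S-WASP"),
    (("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "C", "PPR", "WH2", "C"),
     "WASP", "tandem-PPR-VC"),
]


class TestClassifyGrammar:
    @pytest.mark.parametrize("kinds,family,subtype", RULE_TABLE)
    def test_rule_table(self, kinds, family, subtype):
        arch, record = arch_from_string(kinds)
        a = classify(arch, sequence=record.sequence)
        assert (a.family, a.subtype) == (family, subtype)
        assert a.rationale

    def test_empty_architecture_unclassified(self):
        record = ProteinRecord("r", "A" * 50)
        arch = resolve_architecture(record, [])
        a = classify(arch)
        assert (a.family, a.subtype) == ("unclassified", "none")

    def test_wawh_type_ii_needs_cxxc_on_sequence(self):
        kinds = ("SER", "CRIB", "WAID", "CC", "PPR", "WH2", "C", "A")
        arch, record = arch_from_string(kinds)
        plain = classify(arch, sequence=record.sequence)
        assert plain.subtype == "WAWH-I"           # no CxxC pair in poly-A
        seq = "MCAACGGGCTTC" + record.sequence[12:]
        typed = classify(arch, sequence=seq)
        assert typed.subtype == "WAWH-II"

    def test_wh1_dominates_wawh(self):
        """A WH1-bearing protein can never be WAWH."""
        arch, record = arch_from_string(
            ("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "C", "A"))
        assert classify(arch, record.sequence).family == "WASP"

    def test_classify_is_pure(self):
        arch, record = arch_from_string(("WHD", "PPR", "WH2", "C", "A"))
        a = classify(arch, record.sequence)
        b = classify(arch, record.sequence)
        assert a == b

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        ["WH1", "IMD", "WAID", "CRIB", "B", "PPR", "WH2", "C", "A", "SER"]),
        min_size=0, max_size=8))
    def test_short_subtypes_never_carry_full_vca(self, kinds):
        """S-WASP and WAML-short are never assigned when both C and A are
        present."""
        arch, record = arch_from_string(tuple(kinds)) if kinds else \
            (resolve_architecture(ProteinRecord("rec", "A" * 30), []), None)
        a = classify(arch, record.sequence if record else None)
        if a.subtype in ("S-WASP", "WAML-short"):
            assert not ({"C", "A"} <= arch.kinds())


class TestResolveArchitecture:
    def test_overlap_resolution_keeps_higher_score(self):
        record = ProteinRecord("r", "A" * 60)
        calls = [DomainCall("r", "WH2", 10, 29, 11.0),
                 DomainCall("r", "WH2", 12, 31, 9.0)]
        arch = resolve_architecture(record, calls)
        assert [(c.start, c.end) for c in arch.calls] == [(10, 29)]

    def test_vca_group_annotated(self):
        record = ProteinRecord("r", "A" * 200)
        calls = [DomainCall("r", "WH2", 100, 119, 11.0),
                 DomainCall("r", "C", 125, 140, 6.0),
                 DomainCall("r", "A", 150, 170, 1.0)]
        arch = resolve_architecture(record, calls)
        assert len(arch.vca_groups) == 1
        g = arch.vca_groups[0]
        assert (g.start, g.end) == (100, 170)

    def test_call_beyond_sequence_rejected(self):
        record = ProteinRecord("r", "A" * 20)
        with pytest.raises(ValueError, match="beyond"):
            resolve_architecture(record, [DomainCall("r", "WH2", 10, 40, 1.0)])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 180), st.integers(1, 40),
                              st.floats(0.1, 20)), min_size=0, max_size=12))
    def test_greedy_selection_matches_direct_recomputation(self, raw):
        record = ProteinRecord("r", "A" * 240)
        calls = [DomainCall("r", "WH2", s, min(240, s + l - 1), round(sc, 3))
                 for s, l, sc in raw]
        arch = resolve_architecture(record, calls)
        # direct recomputation of the greedy rule
        expected = []
        for cand in sorted(calls, key=lambda c: (-c.score, c.start, -c.length)):
            if all(not cand.overlaps(k) for k in expected):
                expected.append(cand)
        assert set(arch.calls) == set(expected)
        for a, b in zip(arch.calls, arch.calls[1:]):
            assert a.end < b.start


class TestCompleteness:
    POLICY = CompletenessPolicy(expected_lengths={"WASP": 500})

    @pytest.mark.parametrize("length,expected", [
        (500, "Complete"), (496, "Complete"),     # within the 1% tolerance
        (480, "Partial"), (475, "Partial"),       # m = 0.04 .. 0.05
        (350, "Fragment"),                        # m = 0.30
    ])
    def test_thresholds(self, length, expected):
        record = ProteinRecord("r", "A" * length)
        a = FamilyAssignment("r", "WASP", "canonical", rationale="x")
        assert assess_completeness(record, a, self.POLICY) == expected

    def test_missing_expected_length_warns_complete(self):
        record = ProteinRecord("r", "A" * 100)
        a = FamilyAssignment("r", "WAML", "canonical", rationale="x")
        with pytest.warns(UserWarning, match="no expected length"):
            assert assess_completeness(record, a, self.POLICY) == "Complete"


class TestPseudogene:
    def test_clean_orf(self):
        assert flag_pseudogene("ATGAAATAA") == (False, 0)

    def test_internal_stop_counts(self):
        flag, count = flag_pseudogene("ATGTAAAAATAA")
        assert count >= 1 and flag is False

    def test_multiply_disabled_cds_flagged(self):
        # no ATG, no terminal stop, internal stop, length % 3 != 0
        flag, count = flag_pseudogene("AAATAAAAAA")
        assert count == 4 and flag is True

    def test_empty_cds_rejected(self):
        with pytest.raises(ValueError):
            flag_pseudogene("")
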