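import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from waspfam.detectors import (CompositionWindowSpec, basic_region_spec,
                               c_domain_patterns, charged_region_spec,
                               crib_pattern, ppr_spec, scan_acidic_terminus,
                               scan_c_domain, scan_coiled_coil,
                               scan_composition, scan_crib, scan_pattern,
                               wh2_pattern)
from waspfam.simulate import _emit_charged, _emit_crib

import oracles

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPatternScan:
    def test_wh2_constructed_example(self):
        calls = scan_pattern("MLASIKAAAAAAAAAALKKV", wh2_pattern((8, 12)))
        assert [(c.start, c.end) for c in calls] == [(1, 20)]
        assert calls[0].score == 10.0          # no V/I/F in the poly-A linker

    def test_wh2_linker_bonus(self):
        calls = scan_pattern("MLASIKAAAAVAAAAALKKV", wh2_pattern((8, 12)))
        assert calls and calls[0].score == 11.0

    def test_no_match_on_homopolymer(self):
        assert scan_pattern("G" * 20, wh2_pattern()) == []

    def test_c_domain_constructed_example(self):
        calls = scan_c_domain("VAAAIAAALKKY")
        assert [(c.start, c.end) for c in calls] == [(1, 12)]

    def test_crib_on_poly_a_is_empty(self):
        assert scan_crib("A" * 500) == []

    def test_planted_crib_recovered(self):
        rng = np.random.default_rng(5)
        crib = _emit_crib(rng)
        seq = "G" * 37 + crib + "G" * 25
        calls = scan_crib(seq)
        assert (38, 37 + len(crib)) in [(c.start, c.end) for c in calls]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        """Scanner output equals exhaustive offset x gap-length enumeration
        on seeded random sequences."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA), size=1000))
        for pat in (wh2_pattern(), crib_pattern(), *c_domain_patterns()):
            got = {(c.start, c.end): c.score for c in scan_pattern(seq, pat)}
            assert got == oracles.pattern_matches(seq, pat.positions, pat.gaps)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="VILMASKRQGEDT", min_size=10, max_size=120))
    def test_oracle_equivalence_property(self, seq):
        pat = wh2_pattern((2, 6))
        got = {(c.start, c.end): c.score for c in scan_pattern(seq, pat)}
        assert got == oracles.pattern_matches(seq, pat.positions, pat.gaps)


class TestCompositionScan:
    def test_basic_region_example(self):
        spec = CompositionWindowSpec("basic", "B", frozenset("KR"), 8, 0.5)
        calls = scan_composition("AAKRKRKRKRKRAA", spec)
        assert [(c.start, c.end, c.score) for c in calls] == [(3, 12, 1.0)]

    def test_ppr_on_non_proline_is_empty(self):
        assert scan_composition("MMMMMMMM", ppr_spec()) == []

    def test_short_sequence_is_empty(self):
        assert scan_composition("KR", basic_region_spec()) == []

    def test_planted_charged_block_covered(self):
        rng = np.random.default_rng(9)
        block = _emit_charged(rng, 800)
        seq = "".join(rng.choice(list("AGQNT"), size=100)) + block \
            + "".join(rng.choice(list("AGQNT"), size=100))
        calls = scan_composition(seq, charged_region_spec())
        assert len(calls) == 1
        call = calls[0]
        covered = min(call.end, 900) - max(call.start, 101) + 1
        assert covered >= 0.95 * 800
        assert call.score >= 0.8

    def test_runs_never_overlap_and_meet_threshold(self):
        rng = np.random.default_rng(3)
        spec = basic_region_spec(merge_gap=1)   # unmerged runs
        for _ in range(25):
            seq = "".join(rng.choice(list("KRAG"), size=300))
            calls = scan_composition(seq, spec)
            for a, b in zip(calls, calls[1:]):
                assert a.end < b.start
            for c in calls:
                # overall fraction within the documented windowing slack
                slack = 2 * spec.window * (1 - spec.fraction) / c.length
                assert c.score >= spec.fraction - slack


class TestAcidicTerminus:
    @pytest.mark.parametrize("tail,cls", [
        ("DDEEDDEEW", "W"),
        ("DDEEDDEEF", "F_or_Y"),
        ("DDEEDDEEDD", "none"),
    ])
    def test_aromatic_classes(self, tail, cls):
        call, got = scan_acidic_terminus("AGAG" * 10 + tail)
        assert call is not None and call.kind == "A"
        assert got == cls

    def test_no_acidic_terminus(self):
        call, cls = scan_acidic_terminus("AGAG" * 20)
        assert call is None and cls == "none"

    def test_distant_acidic_segment_rejected(self):
        seq = "DDEEDDEEDD" + "AGAG" * 10   # acidic block far from terminus
        call, _ = scan_acidic_terminus(seq)
        assert call is None


class TestCoiledCoil:
    def test_perfect_heptads_one_call(self):
        calls = scan_coiled_coil("LAAALAA" * 8)
        assert len(calls) == 1
        assert calls[0].start == 1 and calls[0].end >= 50
        assert calls[0].score == 1.0

    def test_too_short_is_empty(self):
        assert scan_coiled_coil("LAAALAA") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA), size=200))
        got = [(c.start, c.end, round(c.score, 9)) for c in scan_coiled_coil(seq)]
        exp = [(s, e, round(sc, 9))
               for s, e, sc in oracles.coiled_coil_calls(seq)]
        assert got == exp


def test_x_never_satisfies_a_class_or_counts_as_target():
    assert scan_pattern("X" * 30, wh2_pattern()) == []
    calls = scan_composition("KRKRXXXXXXKRKR" + "A" * 10, basic_region_spec())
    assert all("X" not in str(c.evidence) or c.score <= 1 for c in calls)
    # an X inside an otherwise perfect window dilutes the fraction
    pure = scan_composition("A" + "KR" * 8 + "A", basic_region_spec())
    with_x = scan_composition("A" + "KR" * 4 + "X" * 2 + "KR" * 3 + "A",
                              basic_region_spec())
    assert pure[0].score == 1.0
    assert not with_x or with_x[0].score < 1.0
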