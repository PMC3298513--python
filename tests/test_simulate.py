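import numpy as np
import pytest

from waspfam.classify import flag_pseudogene
from waspfam.detectors import scan_pattern, wh2_pattern
from waspfam.phylo import SpeciesTree, build_matrix, dollo_reconstruct
from waspfam.pipeline import classify_proteome
from waspfam.simulate import (ARCHITECTURES, GeneratorConfig, generate_cds,
                              generate_proteome, generate_scenario)


class TestGenerateProteome:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(seed=17, n_proteins=15, n_species=4)
        a = generate_proteome(cfg)
        b = generate_proteome(cfg)
        assert [(r.id, r.sequence) for r in a[0]] == \
            [(r.id, r.sequence) for r in b[0]]
        assert a[1] == b[1]

    def test_different_seeds_differ(self):
        a = generate_proteome(GeneratorConfig(seed=1, n_proteins=5))
        b = generate_proteome(GeneratorConfig(seed=2, n_proteins=5))
        assert [r.sequence for r in a[0]] != [r.sequence for r in b[0]]

    def test_truth_coordinates_inside_sequence(self, small_proteome):
        records, truths, _ = small_proteome
        lengths = {r.id: len(r.sequence) for r in records}
        for t in truths:
            for call in t.calls:
                assert 1 <= call.start <= call.end <= lengths[t.record_id]

    def test_planted_wh2_matches_pattern(self, small_proteome):
        records, truths, _ = small_proteome
        seqs = {r.id: r.sequence for r in records}
        pat = wh2_pattern()
        for t in truths:
            for call in t.calls:
                if call.kind != "WH2":
                    continue
                sub = seqs[t.record_id][call.start - 1:call.end]
                spans = [(c.start, c.end) for c in scan_pattern(sub, pat)]
                assert (1, len(sub)) in spans

    def test_single_canonical_wasp_closes_the_loop(self):
        cfg = GeneratorConfig(seed=23, plan=(("Homo", "WASP-canonical"),))
        records, truths, _ = generate_proteome(cfg)
        _, assignments = classify_proteome(records)
        assert assignments[0].family == "WASP"
        assert assignments[0].subtype == "canonical"

    def test_wawh_iii_charged_block_by_construction(self):
        cfg = GeneratorConfig(seed=5, plan=(("Entamoeba", "WAWH-III"),))
        records, truths, _ = generate_proteome(cfg)
        chg = [c for c in truths[0].calls if c.kind == "CHG"][0]
        assert chg.length >= 400
        block = records[0].sequence[chg.start - 1:chg.end]
        frac = sum(ch in "ERK" for ch in block) / len(block)
        assert frac >= 0.8

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            generate_proteome(GeneratorConfig(seed=1,
                                              plan=(("X", "NOT-A-FAMILY"),)))

    def test_truncation_classes_recorded(self):
        cfg = GeneratorConfig(seed=31, n_proteins=60, partial_prob=0.3,
                              fragment_prob=0.3)
        records, truths, _ = generate_proteome(cfg)
        classes = {t.completeness for t in truths}
        assert {"Complete", "Partial", "Fragment"} <= classes
        lengths = {r.id: len(r.sequence) for r in records}
        for t in truths:
            for call in t.calls:
                assert call.end <= lengths[t.record_id]


class TestScenario:
    TREE = "(((S1,S2)CladeA,(S3,S4)CladeB)Inner,S5)Root;"

    def test_loss_propagates_to_descendants(self):
        tree = SpeciesTree.read(self.TREE)
        plan, _ = generate_scenario(
            tree, {"WASH": {"gain": "Root", "losses": ["CladeA"]}})
        species_with_wash = {sp for sp, _ in plan}
        assert species_with_wash == {"S3", "S4", "S5"}

    def test_no_events_means_everyone_has_everything(self):
        tree = SpeciesTree.read(self.TREE)
        plan, _ = generate_scenario(
            tree, {"WASP": {"gain": "Root", "losses": []}})
        assert {sp for sp, _ in plan} == {"S1", "S2", "S3", "S4", "S5"}

    def test_two_gains_rejected(self):
        tree = SpeciesTree.read(self.TREE)
        with pytest.raises(ValueError, match="one gain"):
            generate_scenario(
                tree, {"WASP": {"gain": ["CladeA", "CladeB"], "losses": []}})

    def test_end_to_end_event_recovery(self):
        """generate_scenario -> generate_proteome -> classify ->
        dollo_reconstruct returns exactly the planted events (noise 0),
        including a whole-clade WASH loss."""
        tree = SpeciesTree.read(self.TREE)
        events = {
            "WASP": {"gain": "Root", "losses": []},
            "WASH": {"gain": "Root", "losses": ["CladeA"]},
            "WHAMM": {"gain": "CladeB", "losses": []},
        }
        plan, _ = generate_scenario(tree, events)
        records, truths, smap = generate_proteome(
            GeneratorConfig(seed=13, plan=plan))
        _, assignments = classify_proteome(records)
        matrix = build_matrix(assignments, smap,
                              all_species=tree.leaf_labels())
        rec = dollo_reconstruct(tree, matrix)
        for fam, ev in events.items():
            got = rec.per_family[fam]
            assert got.gain == ev["gain"]
            assert sorted(got.losses) == sorted(ev["losses"])


class TestGenerateCDS:
    def _record(self):
        from waspfam.records import ProteinRecord
        return ProteinRecord("p", "MAKVLDEW")

    def test_clean_cds_has_no_disablements(self):
        cds = generate_cds(self._record())
        assert flag_pseudogene(cds) == (False, 0)

    def test_two_internal_stops_flagged(self):
        rng = np.random.default_rng(1)
        cds = generate_cds(self._record(),
                           ("internal_stop", "internal_stop"), rng=rng)
        flag, count = flag_pseudogene(cds)
        assert count >= 2 and flag

    def test_frameshift_breaks_frame(self):
        cds = generate_cds(self._record(), ("frameshift",))
        assert len(cds) % 3 != 0
        _, count = flag_pseudogene(cds)
        assert count >= 1

    def test_missing_start_and_stop(self):
        cds = generate_cds(self._record(), ("no_start", "no_stop"))
        flag, count = flag_pseudogene(cds)
        assert count >= 2 and flag
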