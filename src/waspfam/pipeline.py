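"""End-to-end annotation: detectors + profile scans -> architectures ->
family assignments.

The pipeline is a thin composition of the library modules, parameterised
by a :class:`~waspfam.config.RunConfig`.  Detector outputs are invariant
under record reordering; every stage is deterministic.
"""

from __future__ import annotations

from . import detectors
from .classify import (Architecture, CompletenessPolicy, FamilyAssignment,
                       assess_completeness, classify, resolve_architecture)
from .config import RunConfig
from .profiles import ProfileModel, scan_profile, scan_split_profile
from .records import DomainCall, ProteinRecord
from .simulate import DomainLibrary


def build_profile_set(config: RunConfig | None = None,
                      library: DomainLibrary | None = None,
                      ) -> dict[str, ProfileModel]:
    """Profiles for the N-terminal family domains and family motifs.

    By default these come from the synthetic :class:`DomainLibrary` seeded
    by ``[generator] library_seed``; callers working with real sequences
    should build profiles from their own seed alignments instead
    (:func:`waspfam.profiles.build_profile`) and pass them to
    :func:`annotate_record`.
    """
    config = config or RunConfig()
    if library is None:
        gen = config.section("generator")
        library = DomainLibrary(gen["library_seed"], gen["library_n_seqs"],
                                gen["library_divergence"])
    prof = config.section("profiles")
    return library.profiles(prof["pseudocount"], prof["min_column_occupancy"])


def annotate_record(record: ProteinRecord, profiles: dict[str, ProfileModel],
                    config: RunConfig | None = None) -> list[DomainCall]:
    """Run every detector and profile scan on one record (raw calls:
    overlaps are retained for the classifier to resolve)."""
    config = config or RunConfig()
    det = config.section("detectors")
    prof = config.section("profiles")
    seq, rid = record.sequence, record.id
    calls: list[DomainCall] = []

    calls += detectors.scan_pattern(
        seq, detectors.wh2_pattern((det["wh2_gap_min"], det["wh2_gap_max"])), rid)
    calls += detectors.scan_c_domain(seq, rid, det["c_flank_gap_max"])
    calls += detectors.scan_crib(seq, rid,
                                 (det["crib_gap_min"], det["crib_gap_max"]))
    calls += detectors.scan_composition(
        seq, detectors.basic_region_spec(det["basic_window"],
                                         det["basic_fraction"],
                                         det["merge_gap"]), rid)
    calls += detectors.scan_composition(
        seq, detectors.ppr_spec(det["ppr_window"], det["ppr_fraction"],
                                det["merge_gap"]), rid)
    calls += detectors.scan_composition(
        seq, detectors.serine_rich_spec(det["ser_window"], det["ser_fraction"],
                                        det["merge_gap"]), rid)
    calls += detectors.scan_composition(
        seq, detectors.charged_region_spec(det["charged_window"],
                                           det["charged_fraction"]), rid)
    calls += detectors.scan_coiled_coil(seq, rid, det["cc_window"],
                                        det["cc_fraction"])

    # acidic segments: genome-wide (for internal/tandem A) + terminal scan
    internal_a = detectors.scan_composition(
        seq, detectors.acidic_internal_spec(det["acidic_window"],
                                            det["acidic_internal_fraction"]),
        rid)
    terminal_a, _cls = detectors.scan_acidic_terminus(
        seq, rid, det["acidic_tail"], det["acidic_window"],
        det["acidic_fraction"], det["acidic_end_offset"])
    if terminal_a is not None:
        internal_a = [c for c in internal_a if not c.overlaps(terminal_a)]
        calls.append(terminal_a)
    calls += internal_a

    # a >=200-residue charged region is a low-complexity segment: basic or
    # acidic windows inside it and short motif hits straddling its edges
    # are composition noise, not independent domains — suppress them so
    # they cannot evict the CHG call during overlap resolution
    chg = [c for c in calls if c.kind == "CHG"]
    if chg:
        calls = [c for c in calls
                 if c.kind == "CHG"
                 or not any(c.overlaps(g) for g in chg)]

    tf = prof["score_threshold_fraction"]
    for kind, model in profiles.items():
        if kind in ("WMD_N", "WMD_C"):
            continue
        calls += scan_profile(seq, model, record_id=rid, threshold_fraction=tf)
    if "WMD_N" in profiles and "WMD_C" in profiles:
        calls += scan_split_profile(
            seq, profiles["WMD_N"], profiles["WMD_C"], kind="WMD",
            gap_range=(prof["wmd_gap_min"], prof["wmd_gap_max"]),
            record_id=rid, threshold_fraction=tf)
    return calls


def classify_record(record: ProteinRecord, calls: list[DomainCall],
                    config: RunConfig | None = None,
                    policy: CompletenessPolicy | None = None,
                    ) -> tuple[Architecture, FamilyAssignment]:
    config = config or RunConfig()
    cls = config.section("classifier")
    arch = resolve_architecture(record, calls, cls["vca_max_gap"])
    assignment = classify(arch, sequence=record.sequence,
                          terminal_a_offset=cls["terminal_a_offset"],
                          chg_min_length=cls["chg_min_length"],
                          cxxc_scan_len=cls["cxxc_scan_len"],
                          triple_max_gap=cls["triple_max_gap"])
    assignment = FamilyAssignment(
        assignment.record_id, assignment.family, assignment.subtype,
        completeness=(assess_completeness(record, assignment, policy)
                      if policy and assignment.family != "unclassified"
                      else "Complete"),
        pseudogene=False, rationale=assignment.rationale,
        architecture=assignment.architecture, species=record.species)
    return arch, assignment


def classify_proteome(records: list[ProteinRecord],
                      profiles: dict[str, ProfileModel] | None = None,
                      config: RunConfig | None = None,
                      policy: CompletenessPolicy | None = None,
                      ) -> tuple[dict, list[FamilyAssignment]]:
    """Annotate and classify every record.

    Returns (record_id -> raw calls, assignments in input order).
    """
    config = config or RunConfig()
    if profiles is None:
        profiles = build_profile_set(config)
    all_calls: dict[str, list[DomainCall]] = {}
    assignments: list[FamilyAssignment] = []
    for record in records:
        calls = annotate_record(record, profiles, config)
        all_calls[record.id] = calls
        _, assignment = classify_record(record, calls, config, policy)
        assignments.append(assignment)
    return all_calls, assignments
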