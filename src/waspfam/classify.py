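"""Architecture resolution and family/subtype classification.

The detectors deliberately over-report: overlapping calls and isolated
composition windows are expected.  :func:`resolve_architecture` reduces a
record's calls to one ordered, non-overlapping architecture, and
:func:`classify` applies the family grammar:

======  =============================================================
WASP    WH1 followed by a VCA module (CRIB/WAID optional: fungal
        lineages progressively lost them); S-WASP keeps WH1 + CRIB/WAID
        but lacks the VCA; the tandem-PPR-VC subtype repeats the
        (PPR, WH2, C) cassette and lacks the acidic terminus.
WAVE    WHD followed by a VCA module (PPR optional: plant WAVEs
        carry WAM motifs instead).
WASH    WAHD with central + acidic domains (WH2 optional: the
        kinetoplastid variant lacks it; Stramenopiles carry two VCAs
        in tandem).
WHAMM   WMD + poly-proline + VCA.
WAML    IMD + WAID (+ VCA for the full-length form).
WAWH    CRIB/WAID + VCA with *no* family N-terminal domain; subtypes
        I (basic region before the GBD), II (N-terminal CxxC pair,
        serine-rich region and coiled-coil), III (long highly charged
        region between the GBD and the PPR).
======  =============================================================

Rule precedence: an N-terminal family domain always dominates the
GBD-based WAWH rule, so a WH1-bearing protein can never be WAWH.

Classification is tolerant of isolated spurious calls: the "absence"
conditions of the S-WASP/WAML-short/tandem rules are phrased in terms of
the terminal acidic domain and assembled VCA modules rather than any bare
central-domain window, and family rules accept a degraded VCA (terminal A
plus either WH2 or C) so that a single broken motif does not reassign a
family; such matches are marked in the rationale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .records import DomainCall, ProteinRecord

N_TERMINAL_DOMAINS = ("WH1", "WHD", "WAHD", "WMD", "IMD")
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class VCAGroup:
    """One WH2(+)-C-A module assembled from ordered calls."""

    wh2: tuple[DomainCall, ...]
    c: DomainCall
    a: DomainCall

    @property
    def start(self) -> int:
        return self.wh2[0].start if self.wh2 else self.c.start

    @property
    def end(self) -> int:
        return self.a.end


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping domain calls for one record."""

    record_id: str
    length: int
    calls: tuple[DomainCall, ...]
    vca_groups: tuple[VCAGroup, ...] = ()

    @property
    def string(self) -> str:
        return "-".join(c.kind for c in self.calls)

    def kinds(self) -> set[str]:
        return {c.kind for c in self.calls}

    def of_kind(self, kind: str) -> list[DomainCall]:
        return [c for c in self.calls if c.kind == kind]


@dataclass(frozen=True)
class FamilyAssignment:
    record_id: str
    family: str                      # one of FAMILIES or "unclassified"
    subtype: str                     # one of SUBTYPES
    completeness: str = "Complete"   # Complete | Partial | Fragment
    pseudogene: bool = False
    rationale: str = ""
    architecture: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.family == "unclassified" and self.subtype != "none":
            raise ValueError("unclassified records have subtype 'none'")
        if self.family != "unclassified" and not self.rationale:
            raise ValueError("classified records need a rationale")


@dataclass(frozen=True)
class CompletenessPolicy:
    """Length-based completeness: up to 5% missing is 'Partial', more is
    'Fragment'; a ±1% tolerance absorbs ordinary length jitter."""

    expected_lengths: dict | None = None        # family -> expected residues
    partial_max_missing: float = 0.05
    complete_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.partial_max_missing < 1.0):
            raise ValueError("partial_max_missing must be in (0, 1)")


# ---------------------------------------------------------------------------
# Architecture resolution
# ---------------------------------------------------------------------------

def resolve_architecture(record: ProteinRecord, calls: list[DomainCall],
                         vca_max_gap: int = 100) -> Architecture:
    """Greedy overlap resolution: keep calls by (score desc, start asc,
    length desc); annotate in-order WH2(+)-C-A groups within ``vca_max_gap``
    of each other."""
    for c in calls:
        if c.record_id and c.record_id != record.id:
            raise ValueError(f"call {c.kind} belongs to {c.record_id}, "
                             f"not {record.id}")
        if c.end > len(record.sequence):
            raise ValueError(f"{record.id}/{c.kind}: end {c.end} beyond "
                             f"sequence length {len(record.sequence)}")
    ranked = sorted(calls, key=lambda c: (-c.score, c.start, -c.length))
    chosen: list[DomainCall] = []
    for cand in ranked:
        if not any(cand.overlaps(kept) for kept in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: (c.start, c.end))
    groups = _find_vca_groups(chosen, vca_max_gap)
    return Architecture(record.id, len(record.sequence), tuple(chosen), groups)


def _find_vca_groups(calls: list[DomainCall],
                     max_gap: int) -> tuple[VCAGroup, ...]:
    """Assemble disjoint WH2(+)-C-A modules left-to-right.

    Each A is paired with the nearest unused upstream C within ``max_gap``,
    which in turn is paired with the nearest unused upstream WH2 within
    ``max_gap`` (plus any additional WH2 chained immediately upstream)."""
    a_calls = [c for c in calls if c.kind == "A"]
    c_calls = [c for c in calls if c.kind == "C"]
    w_calls = [c for c in calls if c.kind == "WH2"]
    used_c: set[int] = set()
    used_w: set[int] = set()
    groups = []
    for a in a_calls:
        c_pick = None
        for i in range(len(c_calls) - 1, -1, -1):
            c = c_calls[i]
            if i in used_c or c.end >= a.start:
                continue
            if a.start - c.end - 1 <= max_gap:
                c_pick = (i, c)
                break
        if c_pick is None:
            continue
        ci, c = c_pick
        wh2s: list[DomainCall] = []
        anchor = c.start
        for j in range(len(w_calls) - 1, -1, -1):
            w = w_calls[j]
            if j in used_w or w.end >= anchor:
                continue
            if anchor - w.end - 1 <= max_gap:
                wh2s.insert(0, w)
                used_w.add(j)
                anchor = w.start
        if not wh2s:
            continue
        used_c.add(ci)
        groups.append(VCAGroup(tuple(wh2s), c, a))
    return tuple(groups)


# ---------------------------------------------------------------------------
# Family grammar
# ---------------------------------------------------------------------------

_CXXC_RE = re.compile(r"C..C")


def _has_cxxc_pair(sequence: str, scan_len: int = 40) -> bool:
    return len(_CXXC_RE.findall(sequence[:scan_len])) >= 2


def classify(arch: Architecture, sequence: str | None = None,
             terminal_a_offset: int = 15, chg_min_length: int = 400,
             cxxc_scan_len: int = 40, triple_max_gap: int = 100,
             ) -> FamilyAssignment:
    """Assign family and subtype from a resolved architecture.

    ``sequence`` is only consulted for the WAWH type-II CxxC check; all
    other decisions are pure functions of the architecture.
    """
    kinds = arch.kinds()
    has = kinds.__contains__
    vca = arch.vca_groups
    a_calls = arch.of_kind("A")
    terminal_a = [a for a in a_calls
                  if arch.length - a.end <= terminal_a_offset]
    gbd = has("CRIB") or has("WAID")
    # When a family N-terminal domain is present (profile-backed, hence
    # robust), a surviving terminal acidic domain is accepted as evidence
    # of a degraded VCA even if the short WH2/C patterns are broken —
    # mirroring membership calls made on N-terminal homology for proteins
    # with divergent or lost C-terminal motifs.
    degraded_vca = bool(terminal_a)
    ppr_before_a = bool(terminal_a) and any(
        p.end < terminal_a[0].start for p in arch.of_kind("PPR"))
    gbd_vca = bool(vca) or (bool(terminal_a)
                            and (has("WH2") or has("C") or ppr_before_a))

    def result(family: str, subtype: str, why: str) -> FamilyAssignment:
        return FamilyAssignment(arch.record_id, family, subtype,
                                rationale=why, architecture=arch.string)

    # --- N-terminal family domains dominate -------------------------------
    nterm = [c for c in arch.calls if c.kind in N_TERMINAL_DOMAINS]
    nterm_kind = max(nterm, key=lambda c: c.score).kind if nterm else None
    if nterm and len({c.kind for c in nterm}) > 1:
        ambiguity = ";ambiguous-n-terminal-domains=" + \
            ",".join(sorted({c.kind for c in nterm}))
    else:
        ambiguity = ""

    if nterm_kind == "WH1":
        triples = _count_ppr_wh2_c_triples(arch, triple_max_gap)
        if triples >= 2 and not terminal_a:
            return result("WASP", "tandem-PPR-VC",
                          f"WH1 + {triples} tandem PPR-WH2-C repeats, no "
                          "acidic terminus" + ambiguity)
        if gbd and not terminal_a and not vca and not (has("C") and has("A")):
            return result("WASP", "S-WASP",
                          "WH1 + CRIB/WAID without VCA module" + ambiguity)
        if vca:
            return result("WASP", "canonical", "WH1 + VCA module" + ambiguity)
        if degraded_vca:
            return result("WASP", "canonical",
                          "WH1 + degraded VCA evidence (terminal A)"
                          + ambiguity)
        return result("unclassified", "none", "")

    if nterm_kind == "WHD":
        if vca:
            return result("WAVE", "canonical", "WHD + VCA module" + ambiguity)
        if degraded_vca:
            return result("WAVE", "canonical",
                          "WHD + degraded VCA evidence" + ambiguity)
        return result("unclassified", "none", "")

    if nterm_kind == "WAHD":
        if (has("C") and has("A")) or vca or terminal_a:
            if len(vca) >= 2:
                return result("WASH", "tandem-VCA",
                              f"WAHD + {len(vca)} tandem VCA modules" + ambiguity)
            if not has("WH2"):
                return result("WASH", "no-WH2",
                              "WAHD + C/A without WH2" + ambiguity)
            return result("WASH", "canonical", "WAHD + VCA module" + ambiguity)
        return result("unclassified", "none", "")

    if nterm_kind == "WMD":
        if has("PPR") and (vca or degraded_vca):
            return result("WHAMM", "canonical",
                          "WMD + PPR + VCA module" + ambiguity)
        if vca or degraded_vca:
            return result("WHAMM", "canonical",
                          "WMD + VCA module (PPR undetected)" + ambiguity)
        return result("unclassified", "none", "")

    if nterm_kind == "IMD":
        if not has("WAID"):
            return result("unclassified", "none", "")
        if vca or terminal_a or (has("C") and has("A")):
            return result("WAML", "canonical",
                          "IMD + WAID + VCA module" + ambiguity)
        return result("WAML", "WAML-short",
                      "IMD + WAID without PPR/VCA" + ambiguity)

    # --- no family N-terminal domain: WAWH grammar ------------------------
    if gbd and gbd_vca:
        gbd_calls = arch.of_kind("CRIB") + arch.of_kind("WAID")
        gbd_start = min(c.start for c in gbd_calls)
        gbd_end = max(c.end for c in gbd_calls)
        ppr = [p for p in arch.of_kind("PPR") if p.start > gbd_end]
        region_end = min((p.start for p in ppr), default=arch.length)
        if (sequence is not None and _has_cxxc_pair(sequence, cxxc_scan_len)
                and has("SER")
                and any(c.kind == "CC" and c.start > gbd_start
                        and c.end <= region_end + 10 for c in arch.calls)):
            return result("WAWH", "WAWH-II",
                          "no WH1; CxxC pair + Ser-rich region + coiled-coil "
                          "before the PPR")
        chg = [c for c in arch.of_kind("CHG")
               if c.length >= chg_min_length and c.start > gbd_end]
        if chg:
            return result("WAWH", "WAWH-III",
                          f"no WH1; charged region of {chg[0].length} aa "
                          "after the GBD")
        if any(b.end < gbd_start for b in arch.of_kind("B")):
            return result("WAWH", "WAWH-I",
                          "no WH1; basic region before the GBD")
        return result("WAWH", "WAWH-I",
                      "no WH1; GBD + VCA (no type-II/III features; "
                      "type I by default)")

    return result("unclassified", "none", "")


def _count_ppr_wh2_c_triples(arch: Architecture, max_gap: int) -> int:
    """Count disjoint in-order (PPR, WH2, C) cassettes with bounded gaps."""
    ppr = arch.of_kind("PPR")
    wh2 = arch.of_kind("WH2")
    cds = arch.of_kind("C")
    used_w: set[int] = set()
    used_c: set[int] = set()
    count = 0
    for p in ppr:
        w_pick = next((j for j, w in enumerate(wh2)
                       if j not in used_w and w.start > p.end
                       and w.start - p.end - 1 <= max_gap), None)
        if w_pick is None:
            continue
        w = wh2[w_pick]
        c_pick = next((j for j, c in enumerate(cds)
                       if j not in used_c and c.start > w.end
                       and c.start - w.end - 1 <= max_gap), None)
        if c_pick is None:
            continue
        used_w.add(w_pick)
        used_c.add(c_pick)
        count += 1
    return count


# ---------------------------------------------------------------------------
# Completeness and pseudogene assessment
# ---------------------------------------------------------------------------

def assess_completeness(record: ProteinRecord, assignment: FamilyAssignment,
                        policy: CompletenessPolicy) -> str:
    """Classify a record as Complete / Partial / Fragment from its length
    relative to the expected family length."""
    expected = (policy.expected_lengths or {}).get(assignment.family)
    if not expected:
        import warnings
        warnings.warn(f"{record.id}: no expected length for family "
                      f"{assignment.family!r}; assuming Complete")
        return "Complete"
    missing = max(0.0, 1.0 - len(record.sequence) / expected)
    if missing <= policy.complete_tolerance + 1e-9:
        return "Complete"
    if missing <= policy.partial_max_missing + 1e-9:
        return "Partial"
    return "Fragment"


def flag_pseudogene(cds: str, frame: int = 0,
                    min_disablements: int = 2) -> tuple[bool, int]:
    """Count coding disablements in a CDS and flag pseudogene candidates.

    Disablements: internal in-frame stop codons (each counted), missing
    initial ATG, missing terminal stop codon, and a length not divisible by
    three (frame-shift proxy).  ``flag`` is True when the count reaches
    ``min_disablements``.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    if any(ch not in "ACGTN" for ch in cds):
        raise ValueError("CDS must be over A, C, G, T, N")
    body = cds[frame:]
    codons = [body[i:i + 3] for i in range(0, len(body) - 2, 3)]
    in_frame = len(body) % 3 == 0
    count = 0
    if not codons or codons[0] != "ATG":
        count += 1
    if not (in_frame and codons and codons[-1] in STOP_CODONS):
        count += 1
    if not in_frame:
        count += 1
    internal = codons[:-1] if (in_frame and codons) else codons
    count += sum(1 for c in internal[1:] if c in STOP_CODONS)
    return count >= min_disablements, count
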