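"""Seeded synthetic proteomes with ground truth.

Proteins are emitted as N-to-C concatenations of sampled domain instances
joined by background linkers, following the canonical domain architectures
of the six families (and their described variants: S-WASP, tandem repeats,
plant WAVE motifs, the WH2-less WASH, the three WAWH types, the short
WAML).  Every planted element's coordinates, the planted family/subtype,
completeness and pseudogene status are recorded as truth before any
detector runs.

Design notes
------------
* The family N-terminal domains (WH1, WHD, ...) are emitted from a
  synthetic :class:`DomainLibrary`: per-domain random consensus sequences
  with seed alignments at a configurable divergence.  The library is
  seeded independently of the proteome sample (``library_seed``) so two
  proteomes drawn with different seeds share one domain vocabulary — as
  real proteomes share real domains.  Users may substitute real seed
  alignments for the synthetic library when classifying real sequences.
* Composition-biased blocks are emitted with deterministic structure
  (pure K/R basic block, pure-P PPR, D/E acidic domain ending in W, a
  charged block with exactly 90% E/R/K) and the ``flank_guard`` linker
  residues adjacent to each block avoid that block's target residues, so
  planted boundaries are well defined.
* WH2 linker (gap) lengths are planted in 6..12, inside the scanner's
  default (6, 14) window; one linker residue is forced to V/I/F, matching
  the near-universal hydrophobic anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import AA20, DomainCall, ProteinRecord
from . import detectors
from .profiles import ProfileModel, build_profile

#: Default lengths of the synthetic profile-detected domains (residues).
PROFILE_DOMAIN_LENGTHS = {
    "WH1": 110, "WHD": 130, "WAHD": 140, "IMD": 180, "WAID": 30,
    "WMD_N": 150, "WMD_C": 110,
    "WAM1": 20, "WAM2": 25, "WAM3": 15, "WAM4": 60,
    "WASHM1": 20, "WASHM2": 20,
}

#: Architecture plans (element sequences) and their expected classification.
ARCHITECTURES: dict[str, tuple[tuple[str, ...], str, str]] = {
    "WASP-canonical":
        (("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "WH2", "C", "A"),
         "WASP", "canonical"),
    "WASP-fungal-noCRIB":
        (("WH1", "B", "WAID", "PPR", "WH2", "C", "A"), "WASP", "canonical"),
    "WASP-yeast-minimal":
        (("WH1", "B", "PPR", "WH2", "C", "A"), "WASP", "canonical"),
    "WASP-single-WH2":
        (("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "C", "A"),
         "WASP", "canonical"),
    "S-WASP":
        (("WH1", "CRIB", "WAID"), "WASP", "S-WASP"),
    "WASP-tandem-PPR-VC":
        (("WH1", "B", "CRIB", "WAID", "PPR", "WH2", "C", "PPR", "WH2", "C"),
         "WASP", "tandem-PPR-VC"),
    "WAVE-canonical":
        (("WHD", "B", "PPR", "WH2", "C", "A"), "WAVE", "canonical"),
    "WAVE-plant":
        (("WHD", "B", "WAM1", "WAM2", "WAM3", "WAM4", "WH2", "C", "A"),
         "WAVE", "canonical"),
    "WASH-canonical":
        (("WAHD", "WASHM1", "WASHM2", "PPR", "WH2", "C", "A"),
         "WASH", "canonical"),
    "WASH-noWH2":
        (("WAHD", "WASHM1", "WASHM2", "PPR", "C", "A"), "WASH", "no-WH2"),
    "WASH-tandem-VCA":
        (("WAHD", "WASHM1", "WASHM2", "PPR", "WH2", "C", "A", "WH2", "C", "A"),
         "WASH", "tandem-VCA"),
    "WHAMM-canonical":
        (("WMD", "CC", "PPR", "WH2", "WH2", "C", "A"), "WHAMM", "canonical"),
    "WAWH-I":
        (("B", "CRIB", "WAID", "PPR", "WH2", "C", "A"), "WAWH", "WAWH-I"),
    "WAWH-II":
        (("CXXC", "SER", "CRIB", "WAID", "CC", "PPR", "WH2", "C", "A"),
         "WAWH", "WAWH-II"),
    "WAWH-III":
        (("CRIB", "WAID", "CHG", "PPR", "WH2", "C", "A"), "WAWH", "WAWH-III"),
    "WAML-canonical":
        (("IMD", "WAID", "PPR", "WH2", "C", "A"), "WAML", "canonical"),
    "WAML-short":
        (("IMD", "WAID"), "WAML", "WAML-short"),
}

#: Default architecture used for each family in tree scenarios.
FAMILY_DEFAULT_ARCH = {
    "WASP": "WASP-canonical", "WAVE": "WAVE-canonical",
    "WASH": "WASH-canonical", "WHAMM": "WHAMM-canonical",
    "WAWH": "WAWH-I", "WAML": "WAML-canonical",
}

#: Residues the linker must avoid near an element, so planted boundaries
#: are well defined (composition targets; hydrophobics around coiled coils).
_FLANK_AVOID = {
    "B": frozenset("KR"), "PPR": frozenset("P"), "SER": frozenset("S"),
    "CHG": frozenset("ERK"), "A": frozenset("DE"), "CC": frozenset("VILMFA"),
}
#: Guard width per element kind; the coiled-coil guard spans a full scan
#: window so spurious heptad windows cannot chain into a neighbouring domain.
_FLANK_GUARD = {"CC": 28}

#: Most-frequent human codon per residue (for CDS reverse translation).
HUMAN_CODONS = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "X": "NNN",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the proteome generator needs; ``seed`` is mandatory."""

    seed: int
    n_species: int = 20
    n_proteins: int = 200
    plan: tuple | None = None         # ((species, arch_name), ...) overrides n_*
    motif_mutation_rate: float = 0.0  # per-position, inside planted elements
    partial_prob: float = 0.0
    fragment_prob: float = 0.0
    pseudogene_prob: float = 0.0
    linker_range: tuple[int, int] = (10, 60)
    flank_guard: int = 20
    wh2_gap_range: tuple[int, int] = (6, 12)
    library_seed: int = 20120208
    library_n_seqs: int = 12
    library_divergence: float = 0.05
    chg_length: int = 810

    def __post_init__(self) -> None:
        for rate in (self.motif_mutation_rate, self.partial_prob,
                     self.fragment_prob, self.pseudogene_prob):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated protein."""

    record_id: str
    species: str
    architecture: str                  # plan name, e.g. "WASP-canonical"
    family: str
    subtype: str
    calls: tuple[DomainCall, ...]
    completeness: str = "Complete"
    pseudogene: bool = False


# ---------------------------------------------------------------------------
# Synthetic domain library
# ---------------------------------------------------------------------------

class DomainLibrary:
    """Random conserved consensus + seed alignment per profile domain."""

    def __init__(self, seed: int = 20120208, n_seqs: int = 12,
                 divergence: float = 0.05,
                 lengths: dict[str, int] | None = None):
        self.seed = seed
        self.n_seqs = n_seqs
        self.divergence = divergence
        self.lengths = dict(lengths or PROFILE_DOMAIN_LENGTHS)
        self._consensus: dict[str, str] = {}
        self._alignments: dict[str, list[ProteinRecord]] = {}
        for i, (kind, length) in enumerate(sorted(self.lengths.items())):
            rng = np.random.default_rng([seed, i])
            consensus = "".join(rng.choice(list(AA20), size=length))
            self._consensus[kind] = consensus
            aln = []
            for s in range(n_seqs):
                seq = list(consensus)
                mutate = rng.random(length) < divergence
                for j in np.flatnonzero(mutate):
                    seq[j] = AA20[rng.integers(20)]
                aln.append(ProteinRecord(f"{kind}_seed{s + 1}", "".join(seq),
                                         species="synthetic"))
            self._alignments[kind] = aln

    def consensus(self, kind: str) -> str:
        return self._consensus[kind]

    def alignment(self, kind: str) -> list[ProteinRecord]:
        return list(self._alignments[kind])

    def profiles(self, pseudocount: float = 1.0,
                 min_column_occupancy: float = 0.5) -> dict[str, ProfileModel]:
        return {kind: build_profile(self.alignment(kind), pseudocount,
                                    min_column_occupancy, name=kind)
                for kind in self.lengths}


# ---------------------------------------------------------------------------
# Element emitters
# ---------------------------------------------------------------------------

def _emit_wh2(rng, gap_range) -> str:
    pat = detectors.wh2_pattern()
    helix = "".join(rng.choice(sorted(cls)) for cls in pat.positions[:6])
    gap_len = int(rng.integers(gap_range[0], gap_range[1] + 1))
    gap = [AA20[rng.integers(20)] for _ in range(gap_len)]
    gap[rng.integers(gap_len)] = rng.choice(list("VIF"))
    anchor = "".join(rng.choice(sorted(cls)) for cls in pat.positions[6:])
    return helix + "".join(gap) + anchor


def _emit_c(rng) -> str:
    hydro = list("VILM")
    parts = [rng.choice(hydro)]
    for _ in range(2):
        parts.append("".join(rng.choice(list("AGSTNQ")) for _ in range(3)))
        parts.append(rng.choice(hydro))
    parts.append("".join(rng.choice(list("AGSTNQ"))
                         for _ in range(int(rng.integers(0, 4)))))
    parts.append("".join(rng.choice(list("KR"))
                         for _ in range(int(rng.integers(2, 4)))))
    parts.append("".join(rng.choice(list("AGSTNQ"))
                         for _ in range(int(rng.integers(0, 4)))))
    parts.append(rng.choice(list("VILMY")))
    return "".join(parts)


def _emit_crib(rng) -> str:
    pat = detectors.crib_pattern()
    out = []
    for idx, cls in enumerate(pat.positions):
        out.append(rng.choice(sorted(cls)))
        if idx < len(pat.gaps):
            lo, hi = pat.gaps[idx]
            g = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            out.append("".join(AA20[rng.integers(20)] for _ in range(g)))
    return "".join(out)


def _emit_block(rng, targets: str, length: int) -> str:
    return "".join(rng.choice(list(targets)) for _ in range(length))


def _emit_charged(rng, length: int) -> str:
    """Exactly 90% E/R/K: every 10th interior position is a non-target."""
    others = [c for c in AA20 if c not in "ERK"]
    seq = [rng.choice(list("ERK")) for _ in range(length)]
    for pos in range(5, length - 1, 10):
        seq[pos] = rng.choice(others)
    return "".join(seq)


def _emit_coiled_coil(rng, n_heptads: int = 9) -> str:
    """Heptads with hydrophobic a/d positions; the element starts on an 'a'
    and ends on a 'd' so its register boundaries are sharp."""
    core = list("LIVM")
    polar = list("EQKRSNDT")
    out = []
    for _ in range(n_heptads):
        for pos in range(7):
            out.append(rng.choice(core) if pos in (0, 3) else rng.choice(polar))
    for pos in range(4):                       # final partial heptad a-b-c-d
        out.append(rng.choice(core) if pos in (0, 3) else rng.choice(polar))
    return "".join(out)


def _emit_cxxc(rng) -> str:
    # spacers avoid serine so the element stays distinct from the adjacent
    # serine-rich region of type-II proteins
    spacer = "".join(rng.choice(list("AGTNQ")) for _ in range(2))
    middle = "".join(rng.choice(list("AGTNQ")) for _ in range(3))
    spacer2 = "".join(rng.choice(list("AGTNQ")) for _ in range(2))
    return f"C{spacer}C{middle}C{spacer2}C"


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def _linker(rng, length: int, left_kind: str | None,
            right_kind: str | None, default_guard: int) -> str:
    out = []
    avoid_left = _FLANK_AVOID.get(left_kind)
    avoid_right = _FLANK_AVOID.get(right_kind)
    guard_left = _FLANK_GUARD.get(left_kind, default_guard)
    guard_right = _FLANK_GUARD.get(right_kind, default_guard)
    for i in range(length):
        avoid: frozenset = frozenset()
        if avoid_left and i < guard_left:
            avoid = avoid | avoid_left
        if avoid_right and length - 1 - i < guard_right:
            avoid = avoid | avoid_right
        choices = [c for c in AA20 if c not in avoid]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _emit_element(rng, kind: str, cfg: GeneratorConfig,
                  library: DomainLibrary) -> tuple[str, str | None]:
    """Return (subsequence, truth-call kind or None)."""
    if kind == "WH2":
        return _emit_wh2(rng, cfg.wh2_gap_range), "WH2"
    if kind == "C":
        return _emit_c(rng), "C"
    if kind == "CRIB":
        return _emit_crib(rng), "CRIB"
    if kind == "A":
        return _emit_block(rng, "DE", 19) + "W", "A"
    if kind == "B":
        return _emit_block(rng, "KR", 15), "B"
    if kind == "PPR":
        return _emit_block(rng, "P", 25), "PPR"
    if kind == "SER":
        return _emit_block(rng, "S", 20), "SER"
    if kind == "CHG":
        return _emit_charged(rng, cfg.chg_length), "CHG"
    if kind == "CC":
        return _emit_coiled_coil(rng), "CC"
    if kind == "CXXC":
        return _emit_cxxc(rng), None    # checked on sequence, not as a call
    if kind == "WMD":
        # low-complexity insertion between the two conserved blocks
        insertion = "".join(rng.choice(list("GSQN")) for _ in range(80))
        return (library.consensus("WMD_N") + insertion
                + library.consensus("WMD_C")), "WMD"
    if kind in library.lengths:
        return library.consensus(kind), kind
    raise ValueError(f"architecture references unknown element {kind!r}")


def default_plan(n_proteins: int = 200, n_species: int = 20) -> tuple:
    """Cycle all architectures over a ring of synthetic species."""
    arch_names = list(ARCHITECTURES)
    return tuple(
        (f"Species_{i % n_species + 1:02d}", arch_names[i % len(arch_names)])
        for i in range(n_proteins)
    )


def generate_proteome(config: GeneratorConfig,
                      ) -> tuple[list[ProteinRecord], list[TruthRecord],
                                 dict[str, tuple[str, tuple[str, ...]]]]:
    """Emit a proteome, its ground truth and the species map.

    Deterministic given ``config.seed``; each protein draws from its own
    child generator so records are independent of plan order.
    """
    library = DomainLibrary(config.library_seed, config.library_n_seqs,
                            config.library_divergence)
    plan = config.plan or default_plan(config.n_proteins, config.n_species)
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    species_map: dict[str, tuple[str, tuple[str, ...]]] = {}

    for i, (species, arch_name) in enumerate(plan):
        if arch_name not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {arch_name!r} in plan")
        elements, family, subtype = ARCHITECTURES[arch_name]
        rng = np.random.default_rng([config.seed, i])
        rec_id = f"syn{i:04d}_{arch_name}"

        parts: list[str] = ["M" + _linker(rng, int(rng.integers(2, 9)),
                                          None, elements[0],
                                          config.flank_guard)]
        pos = sum(len(p) for p in parts)
        calls: list[DomainCall] = []
        for j, kind in enumerate(elements):
            if j > 0:
                lo, hi = config.linker_range
                if "CC" in (elements[j - 1], kind):
                    # keep a full scan window of guarded linker around
                    # coiled coils so heptad windows cannot chain across
                    lo = max(lo, 40)
                    hi = max(hi, lo + 5)
                parts.append(_linker(
                    rng, int(rng.integers(lo, hi + 1)),
                    elements[j - 1], kind, config.flank_guard))
                pos += len(parts[-1])
            sub, call_kind = _emit_element(rng, kind, config, library)
            if call_kind is not None:
                calls.append(DomainCall(rec_id, call_kind, pos + 1,
                                        pos + len(sub), 1.0,
                                        evidence="planted"))
            parts.append(sub)
            pos += len(sub)
        # short tail; A-terminated proteins keep the terminus close
        tail_len = int(rng.integers(0, 6)) if elements[-1] == "A" \
            else int(rng.integers(5, 16))
        parts.append(_linker(rng, tail_len, elements[-1], None,
                             config.flank_guard))
        seq = list("".join(parts))

        # per-motif point mutations
        if config.motif_mutation_rate > 0:
            for call in calls:
                for p in range(call.start - 1, call.end):
                    if rng.random() < config.motif_mutation_rate:
                        seq[p] = AA20[rng.integers(20)]

        completeness = "Complete"
        u = rng.random()
        if u < config.fragment_prob:
            completeness = "Fragment"
            keep = int(len(seq) * (1 - rng.uniform(0.15, 0.45)))
            seq = seq[:max(keep, 30)]
        elif u < config.fragment_prob + config.partial_prob:
            completeness = "Partial"
            keep = int(np.ceil(len(seq) * (1 - rng.uniform(0.015, 0.045))))
            seq = seq[:keep]
        if completeness != "Complete":
            kept = []
            for call in calls:
                if call.end <= len(seq):
                    kept.append(call)
                elif call.start <= len(seq):
                    kept.append(replace(call, end=len(seq)))
            calls = kept

        pseudogene = bool(rng.random() < config.pseudogene_prob)
        sequence = "".join(seq)
        if config.motif_mutation_rate == 0 and completeness == "Complete":
            _self_check(sequence, calls, config)
        record = ProteinRecord(rec_id, sequence, species=species,
                               lineage=("Eukaryota", species))
        records.append(record)
        truths.append(TruthRecord(rec_id, species, arch_name, family, subtype,
                                  tuple(calls), completeness, pseudogene))
        species_map[rec_id] = (species, ("Eukaryota", species))
    return records, truths, species_map


def _self_check(sequence: str, calls: list[DomainCall],
                cfg: GeneratorConfig) -> None:
    """Planted pattern instances must match their MotifPattern."""
    pattern_of = {
        "WH2": detectors.wh2_pattern((cfg.wh2_gap_range[0],
                                      cfg.wh2_gap_range[1] + 2)),
        "CRIB": detectors.crib_pattern(),
    }
    for call in calls:
        pat = pattern_of.get(call.kind)
        if pat is None:
            continue
        sub = sequence[call.start - 1:call.end]
        hits = detectors.scan_pattern(sub, pat)
        if not any(h.start == 1 and h.end == len(sub) for h in hits):
            raise AssertionError(
                f"generator self-check failed: planted {call.kind} at "
                f"{call.start}..{call.end} does not match its pattern")


# ---------------------------------------------------------------------------
# Tree scenarios
# ---------------------------------------------------------------------------

def generate_scenario(tree, events: dict[str, dict],
                      families: list[str] | None = None,
                      ) -> tuple[tuple, dict[str, dict]]:
    """Translate planted gain/loss events into a per-species family plan.

    ``events`` maps family -> {"gain": node_label, "losses": [labels]}.
    Returns (plan usable as ``GeneratorConfig.plan``, the echoed truth).
    A family is present in a leaf iff the gain node lies on its root path
    and no loss node does (below the gain).
    """
    from .phylo import SpeciesTree

    for fam, ev in events.items():
        if isinstance(ev.get("gain"), (list, tuple)):
            raise ValueError(f"{fam}: exactly one gain is allowed")
    plan = []
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node is not None:
            path.append(SpeciesTree.label(node))
            node = node.parent_node
        for fam, ev in events.items():
            gain = ev.get("gain")
            losses = set(ev.get("losses", ()))
            if gain not in path:
                continue
            below_gain = path[:path.index(gain) + 1]
            if losses & set(below_gain):
                continue
            plan.append((SpeciesTree.label(leaf),
                         FAMILY_DEFAULT_ARCH[fam]))
    return tuple(plan), dict(events)


# ---------------------------------------------------------------------------
# CDS generation
# ---------------------------------------------------------------------------

def generate_cds(record: ProteinRecord, disablements: tuple[str, ...] = (),
                 rng=None) -> str:
    """Reverse-translate with the most frequent human codon per residue,
    then inject the requested disablements.

    Disablement names: ``internal_stop``, ``no_start``, ``no_stop``,
    ``frameshift``.  Injection positions are deterministic (mid-sequence)
    unless an ``rng`` is supplied.
    """
    protein = record.sequence
    codons = [HUMAN_CODONS[res] for res in protein]
    if protein[0] != "M":
        codons.insert(0, "ATG")
    codons.append("TAA")
    for d in disablements:
        if d == "internal_stop":
            free = [i for i in range(1, len(codons) - 1)
                    if codons[i] not in ("TAA", "TAG", "TGA")]
            if not free:
                continue
            idx = (free[int(rng.integers(len(free)))] if rng is not None
                   else free[len(free) // 2])
            codons[idx] = "TAA"
        elif d == "no_start":
            codons[0] = "ATT"
        elif d == "no_stop":
            codons[-1] = "AAA"
        elif d == "frameshift":
            idx = len(codons) // 2
            codons[idx] = codons[idx][:2]   # drop one nucleotide
        else:
            raise ValueError(f"unknown disablement {d!r}")
    return "".join(codons)
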