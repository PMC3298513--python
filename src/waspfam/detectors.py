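"""Scanners for the short sequence-defined elements of WASP-family proteins.

Two detector families live here:

* **Degenerate residue-class patterns** (:class:`MotifPattern`,
  :func:`scan_pattern`) for the WH2 domain, the central (C) domain and the
  CRIB motif.  A pattern is an ordered list of residue-class sets with
  bounded unconstrained runs ("gaps") between them; every distinct matching
  span is reported, overlaps included — resolving overlaps is the
  classifier's job.

* **Composition-biased windows** (:class:`CompositionWindowSpec`,
  :func:`scan_composition`) for the basic region, poly-proline region,
  serine-rich region, long charged region and acidic termini: maximal runs
  in which every sliding window reaches a target-residue fraction.

A heptad-periodicity heuristic (:func:`scan_coiled_coil`) rounds out the
set.  Scores are simple documented positives (matched fixed positions, or
observed fractions); no null model or e-value is computed.

``X`` residues never satisfy a residue-class position and never count
toward a composition numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AA_SET, DomainCall

#: Hydrophobic residues whose presence in a WH2 linker earns the score bonus.
LINKER_HYDROPHOBICS = frozenset("VIF")
#: Hydrophobic set for the coiled-coil a/d-position heuristic.
CC_HYDROPHOBICS = frozenset("VILMFA")


# ---------------------------------------------------------------------------
# Degenerate residue-class patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """Ordered residue-class positions with bounded unconstrained runs.

    ``gaps[i]`` is the (min, max) length of the unconstrained run allowed
    between fixed positions ``i`` and ``i + 1``; ``(0, 0)`` means adjacent.
    """

    name: str
    positions: tuple[frozenset, ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.positions) - 1:
            raise ValueError(f"{self.name}: need len(positions)-1 gap slots")
        for cls in self.positions:
            if not cls or not cls <= AA_SET:
                raise ValueError(f"{self.name}: residue classes must be non-empty "
                                 "subsets of the 20-aa alphabet")
        for lo, hi in self.gaps:
            if not (0 <= lo <= hi):
                raise ValueError(f"{self.name}: gap min must be <= max and >= 0")

    @property
    def n_fixed(self) -> int:
        return len(self.positions)

    @property
    def min_length(self) -> int:
        return self.n_fixed + sum(lo for lo, _ in self.gaps)


def _cls(s: str) -> frozenset:
    return frozenset(s)


def wh2_pattern(gap_range: tuple[int, int] = (6, 14)) -> MotifPattern:
    """The WH2 consensus: amphipathic-helix classes, a variable linker and
    the conserved LKKT(V)-type anchor.

    The linker gap range defaults to (6, 14); typical family linkers are
    shorter (4-5) and WASH linkers longer (10), so per-family presets can
    narrow or shift the range via configuration.
    """
    positions = tuple(
        _cls(s) for s in
        ("VILM", "LM", "ASED", "ASDEQ", "IL", "KRQ", "L", "KR", "KR", "VTA")
    )
    gaps = ((0, 0),) * 5 + (tuple(gap_range),) + ((0, 0),) * 3
    return MotifPattern("WH2", positions, gaps)


def c_domain_patterns(flank_gap_max: int = 6) -> tuple[MotifPattern, ...]:
    """The central (C) domain: three large hydrophobic residues each
    separated by three amino acids, a basic doublet or triplet, and a final
    large hydrophobic terminator.

    The spacings around the basic run are not tightly constrained; they are
    bounded by ``flank_gap_max`` (default 0..6).  Doublet and triplet basic
    runs are expressed as two sibling patterns.
    """
    core = tuple(_cls(s) for s in ("VILM",)) + tuple(_cls(s) for s in ("VILM",)) \
        + tuple(_cls(s) for s in ("VILM",))
    variants = []
    for n_basic in (2, 3):
        positions = core + tuple(_cls("KR") for _ in range(n_basic)) + (_cls("VILMY"),)
        gaps = (
            (3, 3), (3, 3),                       # exact x3 spacers in the core
            (0, flank_gap_max),                   # core -> basic run
        ) + ((0, 0),) * (n_basic - 1) + (
            (0, flank_gap_max),                   # basic run -> terminator
        )
        variants.append(MotifPattern("C", positions, gaps))
    return tuple(variants)


def crib_pattern(gap_range: tuple[int, int] = (2, 4)) -> MotifPattern:
    """CRIB (Cdc42/Rac interactive binding) consensus
    I-S-x-P-x(2..4)-F-x-H-x-x-H-V-G with conservative class widening."""
    positions = (
        _cls("IV"), _cls("ST"), _cls("P"), _cls("FYW"),
        _cls("H"), _cls("H"), _cls("VI"), _cls("GA"),
    )
    gaps = (
        (0, 0),          # I-S adjacent
        (1, 1),          # S-x-P
        tuple(gap_range),  # P-x(2..4)-F
        (1, 1),          # F-x-H
        (2, 2),          # H-x-x-H
        (0, 0), (0, 0),  # H-V-G adjacent
    )
    return MotifPattern("CRIB", positions, gaps)


def scan_pattern(sequence: str, pattern: MotifPattern,
                 record_id: str = "") -> list[DomainCall]:
    """Report every distinct span matched by *pattern*.

    Overlapping matches are allowed; spans identical in (start, end) are
    reported once with their best score.  Score = number of matched fixed
    positions, plus 1 if any unconstrained (gap) residue of some matching
    assignment is V, I or F (the linker hydrophobic that docks into the
    actin surface pocket).
    """
    n = len(sequence)
    if n < pattern.min_length:
        return []
    best: dict[tuple[int, int], tuple[float, str]] = {}
    positions, gaps = pattern.positions, pattern.gaps
    k = len(positions)

    def extend(pos: int, idx: int, bonus: bool) -> None:
        # sequence[pos] must match positions[idx]
        if pos >= n or sequence[pos] not in positions[idx]:
            return
        if idx == k - 1:
            span = (start0 + 1, pos + 1)
            score = float(k + (1 if bonus else 0))
            prev = best.get(span)
            if prev is None or score > prev[0]:
                best[span] = (score, sequence[start0:pos + 1])
            return
        lo, hi = gaps[idx]
        for g in range(lo, hi + 1):
            nxt = pos + 1 + g
            if nxt >= n:
                break
            gap_res = sequence[pos + 1:nxt]
            extend(nxt, idx + 1,
                   bonus or any(c in LINKER_HYDROPHOBICS for c in gap_res))

    for start0 in range(n - pattern.min_length + 1):
        extend(start0, 0, False)

    return sorted(
        (DomainCall(record_id, pattern.name, s, e, sc,
                    evidence=f"match={m}")
         for (s, e), (sc, m) in best.items()),
        key=lambda c: (c.start, c.end),
    )


def scan_crib(sequence: str, record_id: str = "",
              gap_range: tuple[int, int] = (2, 4)) -> list[DomainCall]:
    """Scan for the CRIB motif (see :func:`crib_pattern`)."""
    return scan_pattern(sequence, crib_pattern(gap_range), record_id)


def scan_c_domain(sequence: str, record_id: str = "",
                  flank_gap_max: int = 6) -> list[DomainCall]:
    """Scan for the central domain, merging doublet/triplet basic variants."""
    best: dict[tuple[int, int], DomainCall] = {}
    for pat in c_domain_patterns(flank_gap_max):
        for call in scan_pattern(sequence, pat, record_id):
            key = (call.start, call.end)
            if key not in best or call.score > best[key].score:
                best[key] = call
    return sorted(best.values(), key=lambda c: (c.start, c.end))


# ---------------------------------------------------------------------------
# Composition-biased regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionWindowSpec:
    """A composition-biased region detector.

    A run is reported where every sliding window of ``window`` residues has
    a ``targets`` fraction of at least ``fraction``; nearby runs (closer
    than ``merge_gap``) are merged; run boundaries are then refined with a
    short window (``min(window, 12)``, same threshold) and trimmed to
    target residues, bounding the windowing slack by roughly
    ``12 * (1 - fraction)`` residues per side.
    """

    name: str
    kind: str
    targets: frozenset
    window: int
    fraction: float
    merge_gap: int = 10
    anchoring: str = "anywhere"     # or "C-terminal"
    max_end_offset: int = 15        # used when anchoring == "C-terminal"

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"{self.name}: fraction must be in (0, 1]")
        if self.window < 4:
            raise ValueError(f"{self.name}: window length must be >= 4")
        if not self.targets <= AA_SET:
            raise ValueError(f"{self.name}: targets must be canonical residues")


def _refine_run(is_target: np.ndarray, start: int, end: int,
                window: int, fraction: float) -> tuple[int, int] | None:
    """Shrink [start, end] (0-based inclusive) with a short-window pass and
    trim to target residues.  Returns None if the run collapses."""
    w = min(window, 12)
    need = fraction * w
    while end - start + 1 >= w and is_target[start:start + w].sum() < need:
        start += 1
    while end - start + 1 >= w and is_target[end - w + 1:end + 1].sum() < need:
        end -= 1
    while start <= end and not is_target[start]:
        start += 1
    while end >= start and not is_target[end]:
        end -= 1
    if end < start:
        return None
    return start, end


def scan_composition(sequence: str, spec: CompositionWindowSpec,
                     record_id: str = "") -> list[DomainCall]:
    """Report maximal composition-biased runs for *spec* (see class docs).

    Score = target fraction of the reported (refined) run.
    """
    n = len(sequence)
    w = spec.window
    if n < w:
        return []
    is_target = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=bool)
    for ch in spec.targets:
        lut[ord(ch)] = True
    is_target = lut[is_target]
    csum = np.concatenate(([0], np.cumsum(is_target)))
    win_counts = csum[w:] - csum[:-w]
    passing = win_counts >= spec.fraction * w - 1e-12

    # group consecutive passing window starts into candidate runs
    runs: list[tuple[int, int]] = []
    i = 0
    m = len(passing)
    while i < m:
        if passing[i]:
            j = i
            while j + 1 < m and passing[j + 1]:
                j += 1
            runs.append((i, j + w - 1))
            i = j + 1
        else:
            i += 1
    if not runs:
        return []

    # merge runs closer than merge_gap
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < spec.merge_gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))

    calls = []
    for s, e in merged:
        refined = _refine_run(is_target, s, e, w, spec.fraction)
        if refined is None:
            continue
        s, e = refined
        if e - s + 1 < w:
            continue
        if spec.anchoring == "C-terminal" and (n - 1 - e) > spec.max_end_offset:
            continue
        frac = float(is_target[s:e + 1].mean())
        calls.append(DomainCall(
            record_id, spec.kind, s + 1, e + 1, frac,
            evidence=f"fraction={frac:.3f};targets={''.join(sorted(spec.targets))}",
        ))
    return calls


def basic_region_spec(window: int = 8, fraction: float = 0.6,
                      merge_gap: int = 10) -> CompositionWindowSpec:
    """Basic region: many lysine and arginine residues."""
    return CompositionWindowSpec("basic", "B", frozenset("KR"), window, fraction,
                                 merge_gap)


def ppr_spec(window: int = 10, fraction: float = 0.5,
             merge_gap: int = 10) -> CompositionWindowSpec:
    """Poly-proline region."""
    return CompositionWindowSpec("poly-proline", "PPR", frozenset("P"), window,
                                 fraction, merge_gap)


def serine_rich_spec(window: int = 10, fraction: float = 0.5,
                     merge_gap: int = 10) -> CompositionWindowSpec:
    """Serine-rich region (WAWH type-II N-terminal feature)."""
    return CompositionWindowSpec("ser-rich", "SER", frozenset("S"), window,
                                 fraction, merge_gap)


def charged_region_spec(window: int = 200, fraction: float = 0.8,
                        merge_gap: int = 20) -> CompositionWindowSpec:
    """Long highly charged region (WAWH type-III): E/R/K-dominated,
    about 90% over about 800 residues in the described proteins."""
    return CompositionWindowSpec("charged", "CHG", frozenset("ERK"), window,
                                 fraction, merge_gap)


def acidic_internal_spec(window: int = 8, fraction: float = 0.875,
                         merge_gap: int = 6) -> CompositionWindowSpec:
    """Acidic (D/E) segments anywhere in the sequence; supports detection of
    the upstream A of tandem-VCA arrangements.  Stricter than the terminal
    scan because it runs over the whole sequence."""
    return CompositionWindowSpec("acidic-internal", "A", frozenset("DE"),
                                 window, fraction, merge_gap)


def scan_acidic_terminus(sequence: str, record_id: str = "",
                         tail_len: int = 60, window: int = 8,
                         fraction: float = 0.75,
                         max_end_offset: int = 15,
                         ) -> tuple[DomainCall | None, str]:
    """Locate the C-terminal acidic (A) domain and classify its aromatics.

    Searches the terminal ``tail_len`` residues for a D/E-rich segment
    ending within ``max_end_offset`` of the terminus.  The aromatic class
    reflects tryptophan and/or phenylalanine/tyrosine occurring inside the
    segment or in the trailing five residues:

    ``"W"``, ``"F_or_Y"``, ``"W_plus_F_or_Y"`` or ``"none"``.
    """
    n = len(sequence)
    offset = max(0, n - tail_len)
    tail = sequence[offset:]
    spec = CompositionWindowSpec("acidic-terminal", "A", frozenset("DE"),
                                 window, fraction, merge_gap=6,
                                 anchoring="C-terminal",
                                 max_end_offset=max_end_offset)
    calls = scan_composition(tail, spec, record_id)
    if not calls:
        return None, "none"
    call = calls[-1]  # the most C-terminal qualifying segment
    start, end = call.start + offset, call.end + offset
    probe = sequence[start - 1:min(n, end + 5)]
    has_w = "W" in probe
    has_fy = ("F" in probe) or ("Y" in probe)
    if has_w and has_fy:
        cls = "W_plus_F_or_Y"
    elif has_w:
        cls = "W"
    elif has_fy:
        cls = "F_or_Y"
    else:
        cls = "none"
    out = DomainCall(record_id, "A", start, end, call.score,
                     evidence=f"{call.evidence};terminal;aromatic={cls}")
    return out, cls


# ---------------------------------------------------------------------------
# Coiled-coil heuristic
# ---------------------------------------------------------------------------

def scan_coiled_coil(sequence: str, record_id: str = "",
                     window: int = 28, threshold: float = 0.6,
                     hydrophobics: frozenset = CC_HYDROPHOBICS,
                     ) -> list[DomainCall]:
    """Heptad heuristic: for each ``window``-residue window and each of the
    7 heptad frames, score the fraction of hydrophobic residues at the a/d
    positions; merge overlapping windows whose best-frame fraction reaches
    ``threshold``.  Score of a merged call = best window score inside it.

    Each merged run is trimmed to its heptad-register support: the first
    and last hydrophobic residue sitting on an a/d slot of the run's best
    overall frame, so reported boundaries track the register rather than
    the window extent.
    """
    n = len(sequence)
    if n < window:
        return []
    hydro = np.array([c in hydrophobics for c in sequence], dtype=np.int32)
    idx = np.arange(n) % 7
    # per-frame indicator of a/d positions
    frame_scores = np.zeros((7, n - window + 1))
    for f in range(7):
        ad = (idx == f) | (idx == (f + 3) % 7)
        contrib = hydro * ad
        csum = np.concatenate(([0], np.cumsum(contrib)))
        counts = csum[window:] - csum[:-window]
        n_ad = np.concatenate(([0], np.cumsum(ad.astype(np.int64))))
        n_ad = n_ad[window:] - n_ad[:-window]
        with np.errstate(invalid="ignore", divide="ignore"):
            frame_scores[f] = np.where(n_ad > 0, counts / np.maximum(n_ad, 1), 0.0)
    best = frame_scores.max(axis=0)
    passing = best >= threshold - 1e-12
    calls = []
    i = 0
    m = len(passing)
    while i < m:
        if passing[i]:
            j = i
            while j + 1 < m and passing[j + 1]:
                j += 1
            score = float(best[i:j + 1].max())
            lo, hi = i, j + window - 1          # 0-based run extent
            # best overall frame of the run, then trim to its a/d support
            support_counts = [
                int((hydro[lo:hi + 1] * ((idx[lo:hi + 1] == f)
                     | (idx[lo:hi + 1] == (f + 3) % 7))).sum())
                for f in range(7)
            ]
            f = int(np.argmax(support_counts))
            is_support = (hydro[lo:hi + 1] > 0) & \
                ((idx[lo:hi + 1] == f) | (idx[lo:hi + 1] == (f + 3) % 7))
            sup = np.flatnonzero(is_support)
            if len(sup):
                start, end = lo + int(sup[0]), lo + int(sup[-1])
                calls.append(DomainCall(
                    record_id, "CC", start + 1, end + 1, score,
                    evidence=f"best_ad_fraction={score:.3f};frame={f}"))
            i = j + 1
        else:
            i += 1
    return calls
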