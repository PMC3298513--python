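"""Column-frequency scoring models and sequence-logo information content.

The family-defining N-terminal domains (WH1, WHD, WAHD, WMD, IMD), the
autoinhibitory WAID domain and the short family-specific motifs (WAM1-4,
the two WASH motifs) are not well captured by short degenerate patterns;
they are detected with ungapped position-specific scoring matrices built
from seed alignments.  Logos report per-column information content in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AA20, GAP_CHAR, DomainCall, ProteinRecord

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class ProfileModel:
    """An ungapped log-odds scoring model over the 20-aa alphabet.

    ``columns[i]`` holds post-pseudocount frequencies for model position i
    (each column sums to 1); ``score_matrix = log2(columns / background)``.
    """

    name: str
    columns: np.ndarray        # (n_cols, 20)
    background: np.ndarray     # (20,)
    score_matrix: np.ndarray   # (n_cols, 20)

    def __post_init__(self) -> None:
        if self.columns.shape[0] < 2:
            raise ValueError(f"{self.name}: profile needs >= 2 columns")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: columns must sum to 1")
        if (self.columns <= 0).any():
            raise ValueError(f"{self.name}: frequencies must be positive")

    def __len__(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.columns.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the best-matching (consensus) sequence."""
        return float(self.score_matrix.max(axis=1).sum())


@dataclass(frozen=True)
class LogoColumn:
    """Per-column logo data: frequencies, information content, sample size."""

    position: int
    frequencies: np.ndarray    # (20,)
    information: float         # bits in [0, log2 20]
    n: int


def build_profile(records: list[ProteinRecord], pseudocount: float = 1.0,
                  min_column_occupancy: float = 0.5,
                  background: np.ndarray | None = None,
                  name: str = "profile") -> ProfileModel:
    """Build a :class:`ProfileModel` from aligned records.

    Columns whose gap fraction exceeds ``1 - min_column_occupancy`` are
    dropped.  Frequencies use a background-proportional pseudocount:
    ``f_a = (c_a + pseudocount * bg_a) / (n_nongap + pseudocount)``.
    """
    if len(records) < 2:
        raise ValueError("build_profile needs >= 2 aligned sequences")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    width = lengths.pop()
    bg = (np.full(20, 1.0 / 20.0) if background is None
          else np.asarray(background, dtype=float))

    counts = np.zeros((width, 20))
    nongap = np.zeros(width)
    for rec in records:
        for j, ch in enumerate(rec.sequence):
            if ch == GAP_CHAR:
                continue
            nongap[j] += 1
            if ch in _AA_INDEX:              # 'X' occupies but never counts
                counts[j, _AA_INDEX[ch]] += 1

    keep = nongap / len(records) >= min_column_occupancy
    if not keep.any():
        raise ValueError("all columns dropped by the occupancy filter")
    counts, nongap = counts[keep], nongap[keep]
    freqs = (counts + pseudocount * bg) / (nongap + pseudocount)[:, None]
    freqs /= freqs.sum(axis=1, keepdims=True)
    score = np.log2(freqs / bg)
    return ProfileModel(name, freqs, bg, score)


def scan_profile(sequence: str, model: ProfileModel,
                 score_threshold: float | None = None,
                 record_id: str = "", kind: str | None = None,
                 threshold_fraction: float = 0.6) -> list[DomainCall]:
    """Best-scoring ungapped non-overlapping placements of *model*.

    The default threshold is ``threshold_fraction`` of the model's
    self-consensus score.  Placements are selected greedily by score
    (ties: leftmost).  'X' residues score the column minimum.  The emitted
    call kind defaults to the model name.
    """
    if score_threshold is None:
        score_threshold = threshold_fraction * model.max_score
    kind = kind or model.name
    w = len(model)
    n = len(sequence)
    if n < w:
        return []
    enc = np.array([_AA_INDEX.get(c, 20) for c in sequence], dtype=np.int64)
    smat = np.hstack([model.score_matrix,
                      model.score_matrix.min(axis=1, keepdims=True)])
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = smat[np.arange(w)[None, :], windows].sum(axis=1)

    order = np.lexsort((np.arange(len(scores)), -scores))
    chosen: list[tuple[int, float]] = []
    taken = np.zeros(len(scores) + w, dtype=bool)
    for off in order:
        sc = scores[off]
        if sc < score_threshold:
            break
        if taken[off:off + w].any():
            continue
        taken[off:off + w] = True
        chosen.append((int(off), float(sc)))
    return sorted(
        (DomainCall(record_id, kind, off + 1, off + w, sc,
                    evidence=f"bits={sc:.2f};threshold={score_threshold:.2f}")
         for off, sc in chosen),
        key=lambda c: c.start,
    )


def scan_split_profile(sequence: str, model_n: ProfileModel,
                       model_c: ProfileModel, kind: str = "WMD",
                       gap_range: tuple[int, int] = (0, 200),
                       record_id: str = "",
                       threshold_fraction: float = 0.6) -> list[DomainCall]:
    """Scan a two-block domain: an N sub-profile and a C sub-profile joined
    by an unconstrained insertion of ``gap_range`` residues (the WMD with
    its low-complexity insertion).  Emits one call spanning both blocks.
    """
    calls_n = scan_profile(sequence, model_n, record_id=record_id, kind=kind,
                           threshold_fraction=threshold_fraction)
    calls_c = scan_profile(sequence, model_c, record_id=record_id, kind=kind,
                           threshold_fraction=threshold_fraction)
    out = []
    used_c: set[int] = set()
    for cn in calls_n:
        paired = None
        for i, cc in enumerate(calls_c):
            if i in used_c:
                continue
            gap = cc.start - cn.end - 1
            if gap_range[0] <= gap <= gap_range[1]:
                paired = (i, cc)
                break
        if paired is None:
            continue
        i, cc = paired
        used_c.add(i)
        out.append(DomainCall(
            record_id, kind, cn.start, cc.end, cn.score + cc.score,
            evidence=f"bits={cn.score + cc.score:.2f};insertion={cc.start - cn.end - 1}aa",
        ))
    return out


def compute_logo(records: list[ProteinRecord],
                 small_sample_correction: bool = False) -> list[LogoColumn]:
    """Per-column frequencies and information content of an alignment.

    IC = log2(20) - H(frequencies), computed over non-gap symbols; with the
    small-sample correction enabled, (20 - 1) / (2 ln2 n) is subtracted and
    the result clamped at 0.  Columns with no non-gap symbols get IC 0.
    """
    if not records:
        raise ValueError("compute_logo needs at least one sequence")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    width = lengths.pop()
    out = []
    for j in range(width):
        counts = np.zeros(20)
        n = 0
        for rec in records:
            ch = rec.sequence[j]
            if ch == GAP_CHAR:
                continue
            n += 1
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        if counts.sum() == 0:
            out.append(LogoColumn(j + 1, counts, 0.0, n))
            continue
        freqs = counts / counts.sum()
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = LOG2_20 - entropy
        if small_sample_correction and n > 0:
            ic -= (20 - 1) / (2 * np.log(2) * n)
        ic = min(max(ic, 0.0), LOG2_20)
        out.append(LogoColumn(j + 1, freqs, ic, n))
    return out
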