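"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation strategies: pattern
matching enumerates every offset and every gap-length assignment; profile
scoring sums per-offset in pure Python; Dollo reconstruction enumerates all
internal-node labelings with exactly one gain edge.
"""

from __future__ import annotations

import itertools


def pattern_matches(sequence: str, positions, gaps,
                    linker_hydrophobics=frozenset("VIF")):
    """All distinct (start, end) spans matching the residue-class pattern,
    each with its best score (fixed positions + linker bonus)."""
    n = len(sequence)
    k = len(positions)
    best = {}

    gap_choices = [range(lo, hi + 1) for lo, hi in gaps]
    for start in range(n):
        stack = [(start, 0, False)]
        # depth-first over gap assignments
        def walk(pos, idx, bonus):
            if pos >= n or sequence[pos] not in positions[idx]:
                return
            if idx == k - 1:
                span = (start + 1, pos + 1)
                score = float(k + (1 if bonus else 0))
                if span not in best or score > best[span]:
                    best[span] = score
                return
            for g in gap_choices[idx]:
                nxt = pos + 1 + g
                if nxt >= n:
                    break
                b = bonus or any(c in linker_hydrophobics
                                 for c in sequence[pos + 1:nxt])
                walk(nxt, idx + 1, b)
        walk(start, 0, False)
    return best


def profile_scores(sequence: str, model) -> list[float]:
    """Per-offset total log-odds, pure Python."""
    from waspfam.profiles import _AA_INDEX
    w = len(model)
    scores = []
    mins = model.score_matrix.min(axis=1)
    for off in range(len(sequence) - w + 1):
        total = 0.0
        for j in range(w):
            ch = sequence[off + j]
            if ch in _AA_INDEX:
                total += model.score_matrix[j, _AA_INDEX[ch]]
            else:
                total += mins[j]
        scores.append(total)
    return scores


def coiled_coil_calls(sequence: str, window: int = 28, threshold: float = 0.6,
                      hydrophobics=frozenset("VILMFA")):
    """Direct recomputation of the heptad heuristic, including the
    register-support trimming, written independently of the vectorised
    implementation."""
    n = len(sequence)
    if n < window:
        return []
    hydro = [c in hydrophobics for c in sequence]

    def frame_fraction(start, f):
        slots = [i for i in range(start, start + window)
                 if i % 7 == f or i % 7 == (f + 3) % 7]
        return sum(hydro[i] for i in slots) / len(slots)

    best = [max(frame_fraction(s, f) for f in range(7))
            for s in range(n - window + 1)]
    calls = []
    s = 0
    while s < len(best):
        if best[s] >= threshold - 1e-12:
            e = s
            while e + 1 < len(best) and best[e + 1] >= threshold - 1e-12:
                e += 1
            lo, hi = s, e + window - 1
            counts = []
            for f in range(7):
                counts.append(sum(
                    hydro[i] for i in range(lo, hi + 1)
                    if i % 7 == f or i % 7 == (f + 3) % 7))
            f = max(range(7), key=lambda x: counts[x])
            support = [i for i in range(lo, hi + 1)
                       if hydro[i] and (i % 7 == f or i % 7 == (f + 3) % 7)]
            if support:
                calls.append((support[0] + 1, support[-1] + 1,
                              max(best[s:e + 1])))
            s = e + 1
        else:
            s += 1
    return calls


def dollo_min_losses(tree, present: set[str]) -> int:
    """Minimum losses over all labelings with exactly one gain edge.

    ``tree`` is a waspfam SpeciesTree whose leaves all carry data; the
    virtual edge above the root starts in the absent state.
    """
    from waspfam.phylo import SpeciesTree

    nodes = tree.nodes()
    internals = [n for n in nodes if not n.is_leaf()]
    leaf_state = {n: (1 if SpeciesTree.label(n) in present else 0)
                  for n in nodes if n.is_leaf()}
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        st = dict(zip(internals, combo))

        def state(n):
            return leaf_state[n] if n.is_leaf() else st[n]

        gains = losses = 0
        for n in nodes:
            parent = n.parent_node
            ps = 0 if parent is None else state(parent)
            if ps == 0 and state(n) == 1:
                gains += 1
            elif ps == 1 and state(n) == 0:
                losses += 1
        if gains == 1 and (best is None or losses < best):
            best = losses
    return best
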