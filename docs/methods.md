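# Methods

## Sequence elements and how they are detected

**Residue-class patterns.** The WH2 domain, the central (C) domain and the
CRIB motif are matched as ordered residue-class patterns with bounded
unconstrained runs. The WH2 pattern is
`[VILM]-[LM]-[ASED]-[ASDEQ]-[IL]-[KRQ]-x(g)-L-[KR]-[KR]-[VTA]`: the
N-terminal amphipathic helix classes, a linker, and the conserved
LKKT(V)-type anchor. Observed linkers range from four to five residues in
most families to about ten in WASH, so the linker gap `g` is configurable
(`[detectors] wh2_gap_min/max`) with default (6, 14) — wide enough to
cover the longer fungal-WASP and WASH linkers while keeping the random
match probability per offset below 1e-8 on a uniform background. The score
of a match is the number of fixed (class) positions, plus one if any linker
residue is V, I or F (the hydrophobic that docks into the actin surface
pocket). The C-domain pattern is `[VILM]-x3-[VILM]-x3-[VILM]-x(0..6)-
[KR]{2,3}-x(0..6)-[VILMY]`; the spacings around the basic run are not
sharply conserved and default to 0..6. CRIB is matched with the canonical
consensus `I-S-x-P-x(2..4)-F-x-H-x-x-H-V-G`, each fixed class widened by
conservative substitutions; the consensus is exposed in configuration
because CRIB definitions vary across the literature. Scanners report
*every* distinct matching span, overlaps included — arbitrating between
overlapping evidence is the classifier's job, not the detector's. Each
scanner is verified against an exhaustive offset × gap-length enumeration
oracle.

**Composition-biased regions.** Basic (K/R), poly-proline (P), serine-rich
(S), charged (E/R/K) and acidic (D/E) regions are reported where every
sliding window of the spec's length reaches the target fraction.
Consecutive passing windows are united, runs closer than `merge_gap` are
merged, boundaries are then refined with a short window (`min(window, 12)`
at the same threshold) and trimmed to target residues. The refinement
bounds the boundary slack of long-window detectors (the 200-residue charged
window would otherwise smear boundaries by ~20 residues); the residual
slack is at most `12·(1−fraction)` residues per side, and the overall
fraction of an unmerged run is at least `fraction − 2·window·(1−fraction) /
length`. Defaults (window, fraction): basic (8, 0.60), poly-proline
(10, 0.50), serine (10, 0.50), charged (200, 0.80), acidic terminal
(8, 0.75) and acidic internal (8, 0.875). The charged-region default
follows the described WAWH type-III regions (~90% E/R/K over ~800
residues); the remaining fractions were set by a false-positive analysis on
the uniform-background null: with a 20-letter uniform background the
per-window probability of, e.g., K/R ≥ 0.4 in an 8-window is ≈5e-3, which
would scatter dozens of spurious basic calls across a 200-protein dataset,
while the chosen thresholds keep the expected spurious count per proteome
below ~1 for every kind that the classification grammar depends on. All
thresholds sit in `[detectors]` and can be lowered for real, composition-
atypical proteomes.

**Acidic terminus.** The A domain is searched in the terminal 60 residues
and must end within 15 residues of the terminus; its aromatic class records
whether a tryptophan and/or phenylalanine/tyrosine occurs inside the
segment or in the trailing five residues (W, F-instead-of-W, both, or the
hydrophobic-free variant seen in some kinetoplastid WASH proteins). A
stricter genome-wide acidic scan supports the internal A of tandem-VCA
arrangements. Acidic or basic windows nested in a detected charged region,
and short motif hits straddling its edges, are treated as part of that
low-complexity region and suppressed.

**Coiled coils.** A deliberately simple heptad heuristic: 28-residue
windows scored over all seven frames by the hydrophobic (V/I/L/M/F/A)
fraction at the a/d positions, threshold 0.6. Merged runs are trimmed to
their register support (first/last hydrophobic a/d of the run's best
frame). On a uniform background roughly a third of windows pass in some
frame, so coiled-coil calls are *advisory*: the classifier only consults
them in one place (WAWH type II) and always in combination with two more
specific features.

## Profile models

Family N-terminal domains (WH1, WHD, WAHD, WMD, IMD), the WAID domain and
the short family motifs (WAM1–4, two WASH motifs) are detected with
ungapped position-specific scoring matrices built from seed alignments.
Frequencies use a background-proportional pseudocount, `f = (c + λ·bg) /
(n + λ)` with λ = 1 and a uniform background by default (no background
model is implied by the data; uniform keeps logos comparable across
families). Columns with more than 50% gaps are dropped. Scan threshold is
60% of the model's self-consensus score — high enough that random 300-mers
essentially never reach it, low enough that a domain tolerates >15%
point divergence before dropping out. The WMD is modelled as two conserved
blocks (WMD-N, WMD-C) joined by an unconstrained insertion of 0–200
residues, reflecting the ~120-residue low-complexity insertion present in
part of the family; a WMD call spans both blocks. Sequence logos report
per-column information `IC = log2(20) − H` over non-gap symbols, with the
optional small-sample correction `(20−1)/(2·ln2·n)`; the mode used is
recorded in the output metadata.

## Classification grammar

Raw calls are reduced to one architecture per protein by greedy selection
(score descending, then start, then length), which works because scores are
stratified by specificity: profile domains score hundreds of bits, pattern
motifs 6–11, composition windows ≤ 1. VCA modules are assembled by pairing
each acidic call with the nearest unused upstream central domain and WH2(s)
within a configurable span.

Rules fire in fixed precedence, and a family N-terminal domain always beats
the GBD-based WAWH rule (WAWH is *defined* by the absence of WH1). Within
WASP: tandem (PPR, WH2, C) cassettes without an acidic terminus →
tandem-PPR-VC; WH1 + CRIB/WAID with no acidic terminus and no VCA →
S-WASP; WH1 + VCA → canonical. WAVE requires WHD + VCA (poly-proline
optional — plant WAVEs lack it). WASH requires WAHD with central + acidic
domains (WH2 optional → the no-WH2 subtype; two VCA modules → tandem-VCA).
WHAMM = WMD + PPR + VCA; WAML = IMD + WAID (± VCA → canonical vs. short).
WAWH subtypes: II requires an N-terminal CxxC pair (checked on the
sequence — CxxC is not a domain call), a serine-rich region and a
coiled-coil before the PPR; III a ≥400-residue charged region after the
GBD; I a basic region before the GBD (and is the default when no
type-specific feature survives).

Two deliberate robustness choices: (1) "absence" conditions are phrased
against the terminal acidic domain and assembled VCA modules rather than
bare central-domain windows, so an isolated spurious window cannot flip a
subtype; S-WASP and WAML-short are additionally never assigned when both C
and A calls are present. (2) When the N-terminal family domain is detected,
a surviving terminal acidic domain is accepted as evidence of a degraded
VCA even if the short WH2/C patterns are broken — mirroring how membership
is argued from N-terminal homology for proteins whose C-terminal motifs are
divergent or lost. Strict rules are evaluated first; degraded matches are
marked in the rationale string.

Completeness is length-based: missing fraction `m = max(0, 1 − len /
expected)` with `m ≤ 5%` = Partial and more = Fragment; a ±1% tolerance
absorbs ordinary jitter, and expected lengths come from a config table or
the median of Complete assignments per family. Pseudogene flagging is
CDS-based only: internal in-frame stops, missing initial ATG, missing
terminal stop and a length not divisible by three each count as one
disablement; two or more flag the record.

## Dollo profiling

The presence/absence analysis is formalised as single-gain (Dollo)
parsimony: each family is gained once, on the edge above the MRCA of all
species carrying it, and lost on the highest edges below the gain whose
entire subtrees lack it. This matches the narrative logic of inferring
ancestral repertoires from presence patterns (the underlying comparative
argument is made by inspection, not by a named algorithm; the model choice
is stated in the output metadata). Species present in the tree but absent
from the matrix are "no data" and never generate losses — unsequenced is
not lost. Pseudogenes are excluded from presence by default. Input trees
are used as rooted at their seed node; an outgroup may be named for
rerooting. The reconstruction is verified against brute-force enumeration
of all single-gain labelings on random trees with up to 8 leaves.

## Synthetic data

The generator emits each protein as an N→C concatenation of sampled domain
instances joined by background linkers (uniform residue frequencies,
lengths uniform on 10–60), following the canonical architectures of all six
families and their described variants (17 architecture plans). Pattern
elements are sampled within their residue classes — WH2 linkers 6–12 long
with a forced V/I/F; composition elements have deterministic structure
(pure K/R, P, or S blocks; a D/E acidic domain ending in tryptophan; a
charged block with exactly 90% E/R/K, the non-target residues placed every
10th position); profile domains are emitted from a synthetic domain
library: per-domain random consensus sequences with 12-sequence seed
alignments at 5% divergence, seeded *independently* of the proteome sample
(`library_seed`) so proteomes drawn with different seeds share one domain
vocabulary. Coiled coils start on an `a` and end on a `d` position. Linker
residues flanking an element avoid that element's target set for 20
residues (28, hydrophobics, around coiled coils) so planted boundaries are
well defined against windowed detectors. Noise knobs: a per-position point
mutation rate inside planted elements, Partial (≤5% trimmed) and Fragment
truncation probabilities, and pseudogene disablement injection via
reverse-translated CDS (most-frequent human codon per residue).

What the generator emulates — and what it does not: element grammar, motif
degeneracy, length variation, degradation, truncation and family losses on
a taxonomy are represented; real linker composition (far from uniform),
genuinely divergent domain sequences, alignment errors, splice variation
and genome-assembly artefacts are not. Passing the recovery suites
therefore demonstrates the internal consistency of detectors, grammar and
reconstruction under controlled conditions, not expected accuracy on real
proteomes; for real data the profile models should be rebuilt from curated
seed alignments and the composition thresholds revisited.

## Problem sizes and numerical choices

The standard recovery suite uses a 200-protein proteome cycling all 17
architectures over 20 species; scanner/oracle agreement uses random
sequences of 50–2000 residues (1000 in the test suite); Dollo/oracle
agreement uses 500 random birth–death trees with ≤8 leaves; these sizes
give stable statistics while keeping the whole suite around ten seconds.
Floating-point ties in completeness use a 1e-9 epsilon; window thresholds
are compared with a 1e-12 tolerance; profile columns are validated to sum
to one within 1e-9. Greedy tie-breaks are deterministic (start ascending,
then length descending), so identical inputs yield byte-identical outputs.

## Known limitations

Ungapped profile scans cannot follow long internal insertions except the
explicitly modelled WMD case. The coiled-coil heuristic is a screen, not a
predictor. The classifier does not reproduce per-species curation
judgments that used genomic context, ESTs and expert inspection, and does
not subdivide WAVE or plant classes (those groupings derive from
phylogenetic trees, which are out of scope as inputs here). Dollo
parsimony by construction cannot represent regain, horizontal transfer, or
copy-number evolution; duplications are reported descriptively from
counts only.
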