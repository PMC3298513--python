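# waspfam

Annotation, classification and phylogenetic profiling of **WASP-family
proteins** — the class I nucleation promoting factors (WASP, WAVE/Scar,
WASH, WHAMM/JMY, and the WASP-like WAWH and WAML proteins) that activate
the ARP2/3 actin-branching complex.

WASP-family proteins are mosaics of very short sequence elements: a
family-defining N-terminal domain (WH1, WHD, WAHD, WMD or IMD), optional
basic/GTPase-binding (CRIB + WAID) regions, low-complexity proline-rich
stretches, and a C-terminal VCA module — one or more G-actin-binding WH2
domains (V), a central connector domain (C) and an acidic terminus (A).
Because the elements are short and degenerate, automated domain databases
miss many of them; `waspfam` implements the element detectors, the
domain-architecture grammar that assigns each protein to a subfamily and
subtype, and the comparative stage that maps family presence/absence onto a
species tree.

## What the package does

* **Degenerate motif scanning** (`waspfam.detectors`). The WH2 domain is
  matched as the residue-class pattern
  `[VILM]-[LM]-[ASED]-[ASDEQ]-[IL]-[KRQ]-x(6..14)-L-[KR]-[KR]-[VTA]`
  (amphipathic helix, variable linker, LKKT(V)-type anchor; +1 score bonus
  for a V/I/F linker residue). The central domain is matched as three large
  hydrophobics each spaced by three residues, a K/R doublet or triplet, and
  a hydrophobic terminator; a widened canonical consensus is used for CRIB.
  Every matching span is reported; overlap resolution happens later.
* **Composition-biased regions**: basic (K/R), poly-proline, serine-rich,
  long highly charged (E/R/K) and acidic (D/E) regions are found as maximal
  runs in which every sliding window exceeds a target fraction, with
  refined, target-trimmed boundaries; the acidic terminus is additionally
  classified by its aromatics (W, F/Y, both, or none). A heptad sliding
  window provides a simple coiled-coil heuristic.
* **Profile models** (`waspfam.profiles`): ungapped log-odds scans for the
  family N-terminal domains built from seed alignments (the WMD is modelled
  as two conserved blocks joined by a low-complexity insertion), plus
  sequence-logo information content (bits per column, optional small-sample
  correction).
* **Architecture grammar** (`waspfam.classify`): greedy overlap resolution
  into one ordered architecture per protein, then family/subtype assignment
  (WASP incl. S-WASP and tandem-PPR-VC; WAVE incl. plant WAVEs; WASH incl.
  WH2-less and tandem-VCA variants; WHAMM; WAML incl. the short form; WAWH
  types I–III), Complete/Partial/Fragment calls (up to 5% missing =
  Partial) and CDS-based pseudogene flagging (internal stops, missing
  start/stop, frame shifts).
* **Phylogenetic profiling** (`waspfam.phylo`): species × family count
  matrices and **Dollo parsimony** gain/loss reconstruction — each family
  is gained once, on the edge above the most recent common ancestor of the
  species that have it, and lost on the minimal set of edges explaining all
  absences. Unsampled species count as "no data", not as losses.
* **Synthetic proteomes** (`waspfam.simulate`): a seeded generator that
  emits proteins as domain concatenations over background linkers for all
  described architectures, with configurable motif degradation, truncation
  and pseudogene disablements, plus tree scenarios with planted gain/loss
  events — ground truth for every pipeline stage.

## Worked example

```python
from waspfam import GeneratorConfig, generate_proteome, classify_proteome

records, truth, species_map = generate_proteome(
    GeneratorConfig(seed=42, n_proteins=6, n_species=3))
calls, assignments = classify_proteome(records)
for a in assignments:
    print(f"{a.record_id:28s} {a.family:5s} {a.subtype:13s} {a.architecture}")
```

prints

```
syn0000_WASP-canonical       WASP  canonical     WH1-B-CRIB-WAID-PPR-WH2-WH2-C-A
syn0001_WASP-fungal-noCRIB   WASP  canonical     WH1-CC-B-WAID-PPR-WH2-CC-C-A
syn0002_WASP-yeast-minimal   WASP  canonical     WH1-B-CC-PPR-WH2-C-A
syn0003_WASP-single-WH2      WASP  canonical     WH1-B-CRIB-CC-WAID-PPR-CC-WH2-C-A
syn0004_S-WASP               WASP  S-WASP        WH1-CC-CRIB-CC-WAID
syn0005_WASP-tandem-PPR-VC   WASP  tandem-PPR-VC WH1-B-CRIB-C-WAID-PPR-WH2-C-PPR-WH2-C
```

Each line is one protein: its resolved N→C architecture string and the
family/subtype the grammar assigns. The fungal variant stays WASP despite
its missing CRIB (the WH1 + VCA rule dominates); the S-WASP keeps WH1 and
the GTPase-binding elements but has no VCA; occasional low-scoring
coiled-coil (`CC`) or central-domain windows in linker regions are
reported by design — detectors over-report and the grammar is written to
be insensitive to isolated spurious windows.

The same pipeline is available from the shell:

```bash
waspfam simulate --seed 42 --out sim/
waspfam classify --in sim/proteome.fasta --species-map sim/species_map.tsv --out calls.tsv
waspfam scan     --in sim/proteome.fasta --out calls.gff
waspfam logo     --in alignment.fasta --out logo.tsv
waspfam profile  --classifications calls.tsv --species-map sim/species_map.tsv \
                 --tree tree.nwk --out-dir profiling/
```

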