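"""Reference statistics of the published curated WASP-family dataset.

The curated pan-eukaryotic dataset behind this package's domain grammar
comprises 1021 manually assembled sequences from 408 organisms.  The
printed per-family counts below serve as consistency inputs: the per-family
totals must sum to the dataset size, the per-logo WH2 sample sizes must sum
to the stated 1080 WH2 domains, and record counts of the curated per-family
alignment files (when a user supplies them) must match the totals.
"""

from __future__ import annotations

import os

from .io import read_fasta

#: Per-family sequence totals of the curated dataset.
FAMILY_TOTALS = {
    "WASP": 400, "WAVE": 344, "WASH": 165, "WHAMM": 76, "WAWH": 19, "WAML": 17,
}

#: Stated dataset size and organism count.
DATASET_TOTAL_SEQUENCES = 1021
DATASET_ORGANISMS = 408

#: Per-family completeness rows (Complete / Partials / Fragments).
COMPLETENESS_COUNTS = {
    "Complete": {"WASP": 316, "WAVE": 312, "WASH": 138, "WHAMM": 47,
                 "WAWH": 18, "WAML": 17},
    "Partials": {"WASP": 33, "WAVE": 9, "WASH": 9, "WHAMM": 7,
                 "WAWH": 0, "WAML": 0},
    "Fragments": {"WASP": 50, "WAVE": 21, "WASH": 17, "WHAMM": 22,
                  "WAWH": 1, "WAML": 0},
}
STATED_COMPLETE = 848
STATED_PARTIALS = 58

#: Sample sizes of the WH2-domain sequence logos.
WH2_LOGO_COUNTS = {
    "WASP-WH2A": 343, "WASP-WH2B": 110, "WAVE": 321, "WASH": 141,
    "WHAMM-WH2A": 63, "WHAMM-WH2B": 69, "WAML": 14, "WAWH": 19,
}
#: Stated number of WH2 domain sequences the consensus pattern is based on.
WH2_TOTAL_SEQUENCES = 1080

#: Sample sizes of the central (C) domain sequence logos.
C_LOGO_COUNTS = {
    "WASP": 349, "WAVE": 321, "WASH": 154, "WHAMM": 69, "WAML": 14, "WAWH": 19,
}


def family_total_sum() -> int:
    return sum(FAMILY_TOTALS.values())


def wh2_logo_sum() -> int:
    return sum(WH2_LOGO_COUNTS.values())


def completeness_sums() -> dict[str, int]:
    return {row: sum(vals.values()) for row, vals in COMPLETENESS_COUNTS.items()}


def count_alignment_records(directory: str,
                            families: tuple[str, ...] = ("WASP", "WAVE",
                                                         "WASH", "WAWH",
                                                         "WAML"),
                            ) -> dict[str, int]:
    """Count sequence records in curated per-family alignment FASTAs.

    Expects ``<directory>/<FAMILY>.fasta`` for each requested family (the
    layout obtained by unpacking the curated alignment archive and naming
    each alignment after its family).  Raises FileNotFoundError when the
    directory or a family file is missing.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(
            f"curated alignment directory not found: {directory}")
    counts = {}
    for fam in families:
        path = os.path.join(directory, f"{fam}.fasta")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing curated alignment: {path}")
        counts[fam] = len(read_fasta(path, aligned=True))
    return counts
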