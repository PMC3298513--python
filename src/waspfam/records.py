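"""Core value types shared across the pipeline.

A :class:`ProteinRecord` is one amino-acid sequence with its species
bookkeeping; a :class:`DomainCall` is one located domain or motif instance.
All coordinates carried by these types are 1-based and inclusive, matching
the GFF3 convention used by every external file the package writes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: The 20 canonical amino acids, alphabetically.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)
#: Legal residue alphabet for unaligned sequences ('X' = assembly-gap ambiguity).
AA_X_SET = AA_SET | {"X"}
GAP_CHAR = "-"

#: Closed vocabulary of domain/motif kinds the detectors may emit.
DOMAIN_KINDS = frozenset(
    [
        "WH2", "C", "A", "CRIB", "WAID", "B", "PPR", "SER", "CHG", "CC",
        "WH1", "WHD", "WAHD", "WMD", "IMD",
        "WAM1", "WAM2", "WAM3", "WAM4",
        "WASHM1", "WASHM2",
    ]
)

FAMILIES = ("WASP", "WAVE", "WASH", "WHAMM", "WAWH", "WAML")

SUBTYPES = (
    "canonical", "S-WASP", "tandem-VCA", "tandem-PPR-VC",
    "WAWH-I", "WAWH-II", "WAWH-III", "WAML-short", "no-WH2", "none",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence.

    Parameters
    ----------
    id:
        Unique identifier within a dataset.
    species:
        Binomial (or any) species name; may be empty before a species map
        is applied.
    lineage:
        Ordered taxon names from root to tip; may be empty.
    sequence:
        Amino acids over the 20-letter alphabet plus ``X``; aligned records
        may additionally contain ``-`` gap characters.
    aligned:
        Whether gap characters are permitted (and length comparisons with
        alignment partners meaningful).
    """

    id: str
    sequence: str
    species: str = ""
    lineage: tuple[str, ...] = ()
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        allowed = AA_X_SET | {GAP_CHAR} if self.aligned else AA_X_SET
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def ungapped(self) -> "ProteinRecord":
        """Return a copy with gap characters removed (identity if none)."""
        if GAP_CHAR not in self.sequence:
            if not self.aligned:
                return self
            return ProteinRecord(self.id, self.sequence, self.species, self.lineage)
        return ProteinRecord(
            self.id, self.sequence.replace(GAP_CHAR, ""), self.species, self.lineage
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainCall:
    """One located domain/motif instance (1-based inclusive coordinates)."""

    record_id: str
    kind: str
    start: int
    end: int
    score: float
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.record_id}/{self.kind}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if not math.isfinite(self.score):
            raise ValueError(f"{self.record_id}/{self.kind}: score must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainCall") -> bool:
        return self.start <= other.end and other.start <= self.end


def check_unique_ids(records: list[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
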