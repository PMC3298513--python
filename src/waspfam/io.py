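"""Readers and writers for the external formats.

FASTA goes through Biopython, tables through pandas/csv, trees through
dendropy (see :mod:`waspfam.phylo`).  All coordinates written are 1-based
inclusive (GFF3 convention); all writers are deterministic, so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import warnings

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (AA_X_SET, GAP_CHAR, DomainCall, ProteinRecord,
                      check_unique_ids)
from .classify import FamilyAssignment


def read_fasta(path, aligned: bool = False) -> list[ProteinRecord]:
    """Read protein FASTA.

    When ``aligned`` is true, gap characters are retained and all sequences
    must have equal length; otherwise gaps are stripped with a warning (so
    curated alignment files can be fed directly to the classifier).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    stripped = False
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        if not aligned and GAP_CHAR in seq:
            seq = seq.replace(GAP_CHAR, "")
            stripped = True
        allowed = AA_X_SET | {GAP_CHAR} if aligned else AA_X_SET
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"record {rid!r}: illegal character {ch!r} at position {pos}")
        records.append(ProteinRecord(rid, seq, aligned=aligned))
    if stripped:
        warnings.warn(f"{path}: gap characters stripped from unaligned input")
    if aligned and len({len(r.sequence) for r in records}) > 1:
        raise ValueError(f"{path}: ragged aligned FASTA")
    return records


def write_fasta(records: list[ProteinRecord], path, wrap: int = 60) -> None:
    check_unique_ids(records)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i:i + wrap] + "\n")


def read_species_map(path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """TSV of (id, species[, semicolon-joined lineage]) -> mapping."""
    mapping: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{line_no}: need at least id and species")
            rid, species = row[0], row[1]
            lineage = tuple(t for t in row[2].split(";") if t) \
                if len(row) > 2 and row[2] else ()
            if rid in mapping:
                raise ValueError(f"{path}:{line_no}: duplicate id {rid!r}")
            mapping[rid] = (species, lineage)
    return mapping


def write_species_map(mapping, path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(mapping):
            species, lineage = mapping[rid]
            fh.write(f"{rid}\t{species}\t{';'.join(lineage)}\n")


def apply_species_map(records: list[ProteinRecord],
                      mapping: dict) -> list[ProteinRecord]:
    """Attach species/lineage to records; warn about unmatched map entries."""
    ids = {r.id for r in records}
    orphans = sorted(set(mapping) - ids)
    if orphans:
        warnings.warn(f"{len(orphans)} species-map ids not in the sequence "
                      f"set (first: {orphans[0]!r})")
    out = []
    for rec in records:
        if rec.id in mapping:
            species, lineage = mapping[rec.id]
            out.append(ProteinRecord(rec.id, rec.sequence, species=species,
                                     lineage=lineage, aligned=rec.aligned))
        else:
            out.append(rec)
    return out


def write_domain_annotations(records: list[ProteinRecord],
                             calls: list[DomainCall], path) -> None:
    """GFF3-style annotation: one feature line per call, deterministic
    (seqid, start, kind) ordering."""
    lengths = {r.id: len(r.sequence) for r in records}
    for call in calls:
        if call.record_id not in lengths:
            raise ValueError(f"call references unknown record {call.record_id!r}")
        if call.end > lengths[call.record_id]:
            raise ValueError(
                f"{call.record_id}/{call.kind}: end {call.end} beyond sequence "
                f"length {lengths[call.record_id]}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in sorted(calls, key=lambda c: (c.record_id, c.start, c.kind)):
            value = (call.evidence.replace("\t", " ")
                     .replace(";", "%3B").replace("=", "%3D"))
            fh.write("\t".join([
                call.record_id, "waspfam", call.kind,
                str(call.start), str(call.end), f"{call.score:.4f}",
                ".", ".", f"evidence={value}",
            ]) + "\n")


def write_classifications(assignments: list[FamilyAssignment], path) -> None:
    with open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "family", "subtype", "completeness",
                         "pseudogene", "architecture", "rationale"])
        for a in sorted(assignments, key=lambda a: a.record_id):
            writer.writerow([a.record_id, a.species, a.family, a.subtype,
                             a.completeness, int(a.pseudogene),
                             a.architecture, a.rationale])


def write_logo_table(columns, path, metadata: str = "") -> None:
    """TSV logo table: position, 20 frequencies, information content, n."""
    from .records import AA20
    with open(path, "w") as fh:
        if metadata:
            fh.write(f"# {metadata}\n")
        fh.write("position\t" + "\t".join(AA20) + "\tinformation_bits\tn\n")
        for col in columns:
            freqs = "\t".join(f"{f:.6f}" for f in col.frequencies)
            fh.write(f"{col.position}\t{freqs}\t{col.information:.6f}\t{col.n}\n")


def write_table(frame: pd.DataFrame, path, index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None,
                 index_label=index_label)
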