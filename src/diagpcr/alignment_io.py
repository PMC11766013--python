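"""Read, validate, write and partition species-labelled multiple sequence
alignments.

An alignment arrives as aligned FASTA (gaps as ``-``). Species labels come
either from the header itself — ``>record_id|Species_name`` or
``>record_id Species name`` — or from a separate two-column TSV label map.
Sequences are stored uppercase with ``U`` normalised to ``T`` (rDNA spacers
are sometimes deposited as RNA). Column coordinates are 0-based half-open
everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from diagpcr.errors import (
    AlignmentShapeError,
    SequenceContentError,
    SpeciesLabelError,
    SpeciesLookupError,
)
from diagpcr.iupac import VALID_CHARS

__all__ = [
    "AlignmentRecord",
    "SpeciesAlignment",
    "read_label_map",
    "read_alignment",
    "write_alignment",
    "partition_by_species",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned sequence with its species label."""

    record_id: str
    species: str
    sequence: str


@dataclass
class SpeciesAlignment:
    """An equal-length, species-labelled nucleotide alignment.

    Invariants (enforced by :meth:`validate`, called on construction via
    :func:`read_alignment` and by :func:`make_alignment`):

    * all sequences have identical length ``n_columns`` ≥ 1;
    * every character is an IUPAC nucleotide code or ``-``;
    * every record has a nonempty species label and a unique id.
    """

    records: list[AlignmentRecord]
    target_species: str | None = None
    _by_species: dict[str, list[AlignmentRecord]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.validate()
        for rec in self.records:
            self._by_species.setdefault(rec.species, []).append(rec)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment contains no records")
        n = len(self.records[0].sequence)
        if n < 1:
            raise AlignmentShapeError("alignment has zero columns")
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.sequence) != n:
                raise AlignmentShapeError(
                    f"record {rec.record_id!r} has length {len(rec.sequence)}, "
                    f"expected {n} (ragged alignment)"
                )
            if not rec.species:
                raise SpeciesLabelError(f"record {rec.record_id!r} has no species label")
            if rec.record_id in seen:
                raise SpeciesLabelError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
            for col, char in enumerate(rec.sequence):
                if char not in VALID_CHARS:
                    raise SequenceContentError(
                        f"record {rec.record_id!r} column {col}: "
                        f"illegal character {char!r}"
                    )

    # -- convenience --------------------------------------------------------
    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        return list(self._by_species)

    def records_for(self, species: str) -> list[AlignmentRecord]:
        if species not in self._by_species:
            raise SpeciesLookupError(
                f"species {species!r} not in alignment "
                f"(present: {', '.join(self._by_species)})"
            )
        return list(self._by_species[species])

    def with_target(self, target: str) -> "SpeciesAlignment":
        self.records_for(target)  # raises if absent
        return replace(self, target_species=target)

    def column(self, col: int) -> list[str]:
        return [rec.sequence[col] for rec in self.records]


def _normalise(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``record_id<TAB>species``; ``#`` starts a comment."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1].strip():
            raise SpeciesLabelError(f"{path}:{lineno}: expected 'record_id<TAB>species'")
        record_id, species = parts[0].strip(), parts[1].strip()
        if record_id in entries:
            raise SpeciesLabelError(f"{path}:{lineno}: duplicate record id {record_id!r}")
        entries[record_id] = species
    return entries


def _species_from_header(record: SeqRecord) -> tuple[str, str]:
    """Parse (record_id, species) from ``id|species`` or ``id species...``."""
    if "|" in record.id:
        record_id, _, species = record.id.partition("|")
        return record_id, species.strip()
    description = record.description.strip()
    if " " in description:
        record_id, _, species = description.partition(" ")
        return record_id, species.strip()
    return record.id, ""


def read_alignment(
    path: str | Path,
    label_map: dict[str, str] | None = None,
    target_species: str | None = None,
) -> SpeciesAlignment:
    """Read an aligned FASTA file into a validated :class:`SpeciesAlignment`.

    Parameters
    ----------
    path:
        Aligned FASTA; all sequences must share one length.
    label_map:
        Optional ``record_id → species`` mapping (see :func:`read_label_map`).
        When absent, species are parsed from the header convention
        ``id|species`` or ``id species``.
    target_species:
        Optional species to mark as the assay target (must be present).
    """
    records: list[AlignmentRecord] = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        record_id, species = _species_from_header(seq_record)
        if label_map is not None:
            if record_id not in label_map:
                raise SpeciesLabelError(
                    f"record {record_id!r} missing from label map"
                )
            species = label_map[record_id]
        elif not species:
            raise SpeciesLabelError(
                f"record {seq_record.id!r}: no species label in header and "
                "no label map given"
            )
        records.append(AlignmentRecord(record_id, species, _normalise(str(seq_record.seq))))
    aln = SpeciesAlignment(records)
    if target_species is not None:
        aln = aln.with_target(target_species)
    return aln


def write_alignment(aln: SpeciesAlignment, path: str | Path) -> None:
    """Write aligned FASTA with ``id|species`` headers (round-trips exactly)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=f"{rec.record_id}|{rec.species}", description="")
        for rec in aln.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def partition_by_species(
    aln: SpeciesAlignment, target: str
) -> tuple[list[AlignmentRecord], dict[str, list[AlignmentRecord]]]:
    """Split records into (target records, non-target records grouped by species).

    Every record lands in exactly one group. A panel with zero non-target
    species is degenerate for specificity work, so it triggers a warning.
    """
    target_records = aln.records_for(target)
    non_target: dict[str, list[AlignmentRecord]] = {
        sp: aln.records_for(sp) for sp in aln.species if sp != target
    }
    if not non_target:
        warnings.warn(
            f"alignment contains only the target species {target!r}; "
            "specificity is undefined",
            stacklevel=2,
        )
    return target_records, non_target


def make_alignment(
    rows: list[tuple[str, str, str]], target_species: str | None = None
) -> SpeciesAlignment:
    """Build an alignment from (record_id, species, sequence) triples in code."""
    aln = SpeciesAlignment(
        [AlignmentRecord(rid, sp, _normalise(seq)) for rid, sp, seq in rows]
    )
    return aln.with_target(target_species) if target_species else aln
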