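"""Domain types and file I/O: protein records, glycosite annotations, FASTA/TSV.

Positions are 1-based everywhere in files, reports and public APIs; Python's
0-based indexing is confined to function bodies.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy residue used to pad windows that run past a protein terminus.
PAD_SYMBOL = "X"

#: Full 21-symbol alphabet used by window encodings; the pad symbol is last.
ALPHABET = AA_ALPHABET + PAD_SYMBOL

#: Ambiguity/nonstandard one-letter codes mapped to the dummy residue.
NONSTANDARD = set("BJOUZ*")


class GlycoType(str, enum.Enum):
    """Glycosylation linkage type, named by the modified atom's element."""

    N = "N"
    O = "O"
    C = "C"


#: Residues that can carry each linkage type: Asn for N-linked, Ser/Thr for
#: O-linked (hydroxyproline/hydroxylysine O-sites are out of scope), Trp for
#: C-linked (mannosylation of the first Trp in its sequon).
ANCHOR_RESIDUES = {
    GlycoType.N: frozenset("N"),
    GlycoType.O: frozenset("ST"),
    GlycoType.C: frozenset("W"),
}


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence over the 20-letter alphabet.

    Nonstandard letters must be cleaned before construction; use
    :meth:`from_raw` for permissive input.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id}: invalid residues {sorted(bad)}; "
                "use ProteinRecord.from_raw to clean nonstandard letters"
            )

    @classmethod
    def from_raw(cls, id: str, sequence: str) -> "ProteinRecord":
        """Build a record from raw input: uppercase, map nonstandard letters to X.

        B, J, O, U, Z and * are replaced by the dummy residue so that residue
        coordinates stay stable; a warning is logged per protein.
        """
        seq = sequence.upper()
        found = set(seq) & NONSTANDARD
        if found:
            logger.warning(
                "protein %s: replacing nonstandard letters %s with %s",
                id, "".join(sorted(found)), PAD_SYMBOL,
            )
            seq = "".join(PAD_SYMBOL if c in NONSTANDARD else c for c in seq)
        return cls(id=id, sequence=seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside protein {self.id} (length {len(self)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class GlycositeAnnotation:
    """An experimentally verified glycosite: protein, 1-based position, type."""

    protein_id: str
    position: int
    glyco_type: GlycoType

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    The id is the first whitespace-delimited token of the header; sequences
    are uppercased and nonstandard letters replaced with the dummy residue.
    """
    path = Path(path)
    records = [
        ProteinRecord.from_raw(rec.id, str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        Path(path),
        "fasta",
    )


_ANNOTATION_COLUMNS = ["protein_id", "position", "glyco_type"]


def read_annotations(path: str | Path) -> list[GlycositeAnnotation]:
    """Read a tab-separated annotation file.

    Expected header: ``protein_id  position  glyco_type`` with 1-based
    positions and glyco_type in {N, O, C}. Lines starting with ``#`` are
    ignored. Exact duplicate rows are collapsed with a warning.
    """
    path = Path(path)
    annotations: list[GlycositeAnnotation] = []
    seen: set[GlycositeAnnotation] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                if header != _ANNOTATION_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_ANNOTATION_COLUMNS}, got {header}"
                    )
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            pid, pos_str, gt_str = (c.strip() for c in row)
            try:
                position = int(pos_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_str!r} is not an integer")
            if position < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1, got {position}")
            try:
                gtype = GlycoType(gt_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unknown glyco_type {gt_str!r}")
            ann = GlycositeAnnotation(pid, position, gtype)
            if ann in seen:
                logger.warning("%s:%d: duplicate annotation %s ignored", path, lineno, ann)
                continue
            seen.add(ann)
            annotations.append(ann)
    if header is None:
        raise ValueError(f"{path}: empty annotation file")
    return annotations


def write_annotations(annotations: Iterable[GlycositeAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow([a.protein_id, a.position, a.glyco_type.value])


@dataclass(frozen=True)
class RejectedAnnotation:
    annotation: GlycositeAnnotation
    reason: str


def validate_annotations(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[GlycositeAnnotation],
    strict: bool = True,
) -> tuple[list[GlycositeAnnotation], list[RejectedAnnotation]]:
    """Partition annotations into (valid, rejected-with-reason).

    An annotation is rejected when its protein is unknown, its position is out
    of range, or the residue at the position is incompatible with the glyco
    type (N-linked on Asn, O-linked on Ser/Thr, C-linked on Trp). With
    ``strict=False`` residue incompatibility only warns and the annotation is
    kept — useful for user data with nonstandard curation.
    """
    by_id = {p.id: p for p in proteins}
    valid: list[GlycositeAnnotation] = []
    rejected: list[RejectedAnnotation] = []
    for ann in annotations:
        protein = by_id.get(ann.protein_id)
        if protein is None:
            rejected.append(RejectedAnnotation(ann, f"unknown protein {ann.protein_id}"))
            continue
        if ann.position > len(protein):
            rejected.append(
                RejectedAnnotation(
                    ann,
                    f"position {ann.position} beyond length {len(protein)}",
                )
            )
            continue
        residue = protein.residue(ann.position)
        allowed = ANCHOR_RESIDUES[ann.glyco_type]
        if residue not in allowed:
            reason = (
                f"residue {residue} at position {ann.position} incompatible with "
                f"{ann.glyco_type.value}-linked site (expected {'/'.join(sorted(allowed))})"
            )
            if strict:
                rejected.append(RejectedAnnotation(ann, reason))
                continue
            logger.warning("%s: %s (kept, strict=False)", ann.protein_id, reason)
        valid.append(ann)
    return valid, rejected
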