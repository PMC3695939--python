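"""Fixed-length overlapping windows ("patterns") around candidate glycosites.

Every residue that could in principle carry a glycan of the requested type
(Asn / Ser+Thr / Trp) yields one window; the window is labelled positive when
the centre residue is an annotated glycosite and negative otherwise —
including anchors sitting inside a valid sequon that are simply not known to
be glycosylated. Windows at protein termini are completed with the dummy
residue X so that all windows share the same length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from glycosite.core import ALPHABET, ANCHOR_RESIDUES, PAD_SYMBOL, GlycoType, ProteinRecord

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PatternConfig:
    """Window geometry: odd length L, centred on the candidate residue."""

    window_length: int = 21
    pad_symbol: str = PAD_SYMBOL

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError(f"window_length must be an odd integer >= 3, got {self.window_length}")

    @property
    def flank(self) -> int:
        """Number of residues on each side of the centre: (L-1)/2."""
        return (self.window_length - 1) // 2


@dataclass(frozen=True)
class Pattern:
    """A labelled window of length L centred on a candidate residue."""

    protein_id: str
    center_position: int  # 1-based position in the unpadded protein
    window: str
    glyco_type: GlycoType
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if len(self.window) % 2 == 0:
            raise ValueError("window length must be odd")
        bad = set(self.window) - set(ALPHABET)
        if bad:
            raise ValueError(f"window contains invalid symbols {sorted(bad)}")
        centre = self.window[len(self.window) // 2]
        if centre not in ANCHOR_RESIDUES[self.glyco_type]:
            raise ValueError(
                f"window centre {centre!r} is not a valid {self.glyco_type.value}-site anchor"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    def __len__(self) -> int:
        return len(self.window)


def pad_sequence(sequence: str, window_length: int) -> str:
    """Append (L-1)/2 dummy residues X at both termini of the sequence."""
    if window_length % 2 == 0:
        raise ValueError(f"window length must be odd, got {window_length}")
    if not sequence:
        raise ValueError("cannot pad an empty sequence")
    flank = (window_length - 1) // 2
    return PAD_SYMBOL * flank + sequence + PAD_SYMBOL * flank


def candidate_sites(protein: ProteinRecord, glyco_type: GlycoType) -> list[int]:
    """1-based positions of every residue compatible with the glyco type."""
    anchors = ANCHOR_RESIDUES[glyco_type]
    return [i for i, res in enumerate(protein.sequence, start=1) if res in anchors]


def build_patterns(
    protein: ProteinRecord,
    annotated_positions: Iterable[int],
    glyco_type: GlycoType,
    config: PatternConfig = PatternConfig(),
) -> list[Pattern]:
    """One window per candidate residue; positive iff the centre is annotated.

    ``annotated_positions`` must be a subset of the candidate sites for this
    protein and type (run :func:`glycosite.core.validate_annotations` first).
    """
    annotated = set(annotated_positions)
    candidates = candidate_sites(protein, glyco_type)
    stray = annotated - set(candidates)
    if stray:
        raise ValueError(
            f"protein {protein.id}: annotated positions {sorted(stray)} are not "
            f"{glyco_type.value}-site candidates"
        )
    padded = pad_sequence(protein.sequence, config.window_length)
    patterns = []
    for pos in candidates:
        # padded index of the window start for 1-based centre pos: (pos-1)
        window = padded[pos - 1 : pos - 1 + config.window_length]
        patterns.append(
            Pattern(
                protein_id=protein.id,
                center_position=pos,
                window=window,
                glyco_type=glyco_type,
                label=POSITIVE if pos in annotated else NEGATIVE,
            )
        )
    return patterns


_PATTERN_COLUMNS = ["protein_id", "center_position", "glyco_type", "label", "window"]


def write_patterns(patterns: Sequence[Pattern], path: str | Path) -> None:
    """Write patterns as TSV, ordered by protein id then position."""
    ordered = sorted(patterns, key=lambda p: (p.protein_id, p.center_position))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PATTERN_COLUMNS)
        for p in ordered:
            writer.writerow(
                [p.protein_id, p.center_position, p.glyco_type.value, p.label, p.window]
            )


def read_patterns(path: str | Path) -> list[Pattern]:
    path = Path(path)
    patterns: list[Pattern] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _PATTERN_COLUMNS:
            raise ValueError(f"{path}: expected header {_PATTERN_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            pid, pos, gtype, label, window = row
            patterns.append(
                Pattern(pid, int(pos), window, GlycoType(gtype), label)
            )
    return patterns
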