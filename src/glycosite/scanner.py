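"""Scanner for canonical and exceptional glycosylation sequons.

Canonical motifs: N-linked glycosylation requires Asn-X-Ser/Thr with X any
residue except Pro; C-linked mannosylation occurs at the first Trp of
W-X-X-W, W-X-X-C or W-X-X-F. No O-linked consensus exists, so O-sites are
not scanned. Rare exceptional motifs (by default N-P-S/T and N-X-C) are kept
in a user-extendable library written in a tiny declarative format::

    N-P-S/T:  N P [ST]
    N-X-C:    N X C

One position per whitespace-separated token: a single residue letter, ``X``
or ``.`` for any residue, ``[ABC]`` for a residue class, ``[^ABC]`` for any
residue except the listed ones. Motifs truncated by the sequence end are not
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from glycosite.core import AA_ALPHABET

CANONICAL = "canonical"
EXCEPTIONAL = "exceptional"


@dataclass(frozen=True)
class SequonMatch:
    protein_id: str
    position: int  # 1-based index of the anchor residue (first motif position)
    motif_text: str
    category: str
    motif_name: str


@dataclass(frozen=True)
class Motif:
    """An anchored short motif: one allowed-residue set per position."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def parse(cls, name: str, spec: str) -> "Motif":
        """Parse the mini-format: tokens separated by spaces or dashes."""
        tokens = spec.replace("-", " ").split()
        if not tokens:
            raise ValueError(f"motif {name!r}: empty specification")
        positions = []
        for token in tokens:
            token = token.upper()
            if token in ("X", "."):
                positions.append(frozenset(AA_ALPHABET))
            elif len(token) == 1 and token in AA_ALPHABET:
                positions.append(frozenset(token))
            elif token.startswith("[^") and token.endswith("]"):
                excluded = set(token[2:-1])
                if not excluded <= set(AA_ALPHABET):
                    raise ValueError(f"motif {name!r}: bad exclusion token {token!r}")
                positions.append(frozenset(AA_ALPHABET) - excluded)
            elif token.startswith("[") and token.endswith("]"):
                allowed = set(token[1:-1])
                if not allowed or not allowed <= set(AA_ALPHABET):
                    raise ValueError(f"motif {name!r}: bad class token {token!r}")
                positions.append(frozenset(allowed))
            else:
                raise ValueError(f"motif {name!r}: cannot parse token {token!r}")
        return cls(name=name, positions=tuple(positions))

    def matches_at(self, sequence: str, start: int) -> bool:
        """True iff the motif matches with its first position at 0-based start."""
        if start + len(self) > len(sequence):
            return False
        return all(
            sequence[start + i] in allowed for i, allowed in enumerate(self.positions)
        )


# canonical motif definitions
_N_CANONICAL = Motif.parse("N-X-S/T", "N [^P] [ST]")
_N_ALL = Motif.parse("N-X-S/T (X unrestricted)", "N X [ST]")
_C_MOTIFS = (
    Motif.parse("W-X-X-W", "W X X W"),
    Motif.parse("W-X-X-C", "W X X C"),
    Motif.parse("W-X-X-F", "W X X F"),
)

#: Exceptional N-sequons named in the main-text literature; extend via files.
DEFAULT_EXCEPTIONAL = (
    Motif.parse("N-P-S/T", "N P [ST]"),
    Motif.parse("N-X-C", "N X C"),
)


@dataclass(frozen=True)
class MotifLibrary:
    motifs: tuple[Motif, ...] = DEFAULT_EXCEPTIONAL

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifLibrary":
        """Load ``name: spec`` lines; ``#`` comments and blank lines ignored."""
        motifs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'name: spec'")
            name, spec = line.split(":", 1)
            motifs.append(Motif.parse(name.strip(), spec))
        return cls(motifs=tuple(motifs))


def _scan(sequence: str, motifs: Iterable[Motif], category: str, protein_id: str) -> list[SequonMatch]:
    matches = []
    for start in range(len(sequence)):
        for motif in motifs:
            if motif.matches_at(sequence, start):
                matches.append(
                    SequonMatch(
                        protein_id=protein_id,
                        position=start + 1,
                        motif_text=sequence[start : start + len(motif)],
                        category=category,
                        motif_name=motif.name,
                    )
                )
    return matches


def scan_n(
    sequence: str, mode: str = "canonical", protein_id: str = ""
) -> list[SequonMatch]:
    """All N-sequon matches; overlapping matches are all reported.

    ``mode='canonical'`` enforces X != Pro; ``mode='nxst_all'`` allows any X
    (the permissive N-X-S/T count some tools report).
    """
    if mode == "canonical":
        motif = _N_CANONICAL
    elif mode == "nxst_all":
        motif = _N_ALL
    else:
        raise ValueError(f"mode must be 'canonical' or 'nxst_all', got {mode!r}")
    return _scan(sequence.upper(), [motif], CANONICAL, protein_id)


def scan_c(sequence: str, protein_id: str = "") -> list[SequonMatch]:
    """All C-mannosylation sequons W-X-X-[W/C/F], anchored at the first Trp."""
    return _scan(sequence.upper(), _C_MOTIFS, CANONICAL, protein_id)


def scan_exceptional(
    sequence: str, library: MotifLibrary = MotifLibrary(), protein_id: str = ""
) -> list[SequonMatch]:
    """All matches of the exceptional-motif library, labelled per motif."""
    return _scan(sequence.upper(), library.motifs, EXCEPTIONAL, protein_id)


def annotate(
    sequence: str,
    matches: Sequence[SequonMatch],
    open_mark: str = "[",
    close_mark: str = "]",
) -> str:
    """Mark matched spans in the sequence; overlapping spans are merged.

    Spans are merged leftmost-first so nested brackets never occur; the
    plain-text analogue of the web rendering that highlights sequons.
    """
    n = len(sequence)
    spans = []
    for m in sorted(matches, key=lambda m: m.position):
        start = m.position - 1
        end = start + len(m.motif_text)
        if start < 0 or end > n:
            raise ValueError(f"match at position {m.position} outside the sequence")
        if spans and start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], end))
        else:
            spans.append((start, end))
    out = []
    prev = 0
    for start, end in spans:
        out.append(sequence[prev:start])
        out.append(open_mark + sequence[start:end] + close_mark)
        prev = end
    out.append(sequence[prev:])
    return "".join(out)


def summarize(
    sequence: str, matches: Sequence[SequonMatch], anchor_residue: str = "N"
) -> dict:
    """Per-protein summary: anchor-residue count and match count per motif."""
    per_motif: dict[str, int] = {}
    for m in matches:
        per_motif[m.motif_name] = per_motif.get(m.motif_name, 0) + 1
    return {
        "anchor_residue": anchor_residue,
        "total_anchors": sequence.upper().count(anchor_residue),
        "total_matches": len(matches),
        "matches_per_motif": per_motif,
    }
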