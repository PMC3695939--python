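"""Deterministic generator of annotated glycoprotein fixtures.

The generator emulates the features of curated glycoprotein data that the
pipeline depends on: proteins of realistic length (50-800 aa), a small
fraction of candidate residues annotated as glycosylated (large
negative-to-positive imbalance), every planted N-site embedded in a valid
Asn-X-Ser/Thr sequon (X != Pro) and every planted C-site in a W-X-X-[W/C/F]
sequon, and configurable position-specific residue enrichment around planted
sites (e.g., Pro at -3/+1/+3 for O-sites). A JSON-able manifest records the
exact ground truth — planted sites and every accidental candidate — so tests
can assert exact expectations.

Everything is reproducible from the single mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from glycosite.core import (
    AA_ALPHABET,
    ANCHOR_RESIDUES,
    GlycoType,
    GlycositeAnnotation,
    ProteinRecord,
    write_annotations,
    write_fasta,
)
from glycosite.patterns import candidate_sites

#: Average SWISS-PROT amino-acid composition (fractions), bundled preset.
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass(frozen=True)
class SignalSpec:
    """Positional enrichment: at `offset` from the site, the probability of
    `residue` is raised by `excess` over its background frequency."""

    offset: int
    residue: str
    excess: float

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("offset 0 is the anchor residue; cannot carry signal")
        if self.residue not in AA_ALPHABET:
            raise ValueError(f"unknown residue {self.residue!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 50
    length_range: tuple[int, int] = (50, 800)
    glyco_type: GlycoType = GlycoType.N
    positive_rate: float = 0.1
    signal: tuple[SignalSpec, ...] = ()
    background: Mapping[str, float] | None = None  # default uniform 1/20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        lo, hi = self.length_range
        if not 5 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")
        if not 0 <= self.positive_rate <= 1:
            raise ValueError(f"positive_rate must be in [0, 1], got {self.positive_rate}")
        object.__setattr__(
            self,
            "signal",
            tuple(s if isinstance(s, SignalSpec) else SignalSpec(*s) for s in self.signal),
        )
        bg = self._background_array()
        for s in self.signal:
            target = bg[AA_ALPHABET.index(s.residue)] + s.excess
            if not 0 <= target <= 1:
                raise ValueError(
                    f"infeasible signal {s}: background {bg[AA_ALPHABET.index(s.residue)]:.3f}"
                    f" + excess {s.excess} outside [0, 1]"
                )

    def _background_array(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        probs = np.array([self.background.get(aa, 0.0) for aa in AA_ALPHABET], dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("background frequencies must be non-negative and sum > 0")
        return probs / probs.sum()


@dataclass(frozen=True)
class SyntheticDataset:
    proteins: tuple[ProteinRecord, ...]
    annotations: tuple[GlycositeAnnotation, ...]
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA + annotation TSV + JSON manifest into a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "annotations": out / "annotations.tsv",
            "manifest": out / "manifest.json",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_annotations(self.annotations, paths["annotations"])
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return paths


def _sequon_extent(glyco_type: GlycoType) -> int:
    """Residues downstream of the anchor fixed by the planted sequon."""
    return {GlycoType.N: 2, GlycoType.O: 0, GlycoType.C: 3}[glyco_type]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate proteins, annotations, and an exact ground-truth manifest.

    Sequences are drawn i.i.d. from the background composition; a seeded
    subset of candidate anchors is promoted to positives by installing the
    type's sequon downstream (and leaving O-sites bare, as no O-consensus
    exists) and resampling residues at the configured signal offsets with the
    enriched probabilities. Promoted sites are spaced so their edits never
    collide; anchors destroyed or created as a side effect of editing are
    reflected in the final candidate list, which is recomputed from the
    finished sequence.
    """
    rng = np.random.default_rng(config.seed)
    bg = config._background_array()
    aa = np.array(list(AA_ALPHABET))
    anchors = ANCHOR_RESIDUES[config.glyco_type]
    sequon_extent = _sequon_extent(config.glyco_type)
    offsets = [s.offset for s in config.signal]
    min_off = min([0] + offsets)
    max_off = max([0, sequon_extent] + offsets)

    proteins: list[ProteinRecord] = []
    annotations: list[GlycositeAnnotation] = []
    manifest_proteins: dict[str, dict] = {}
    lo, hi = config.length_range
    width = len(str(config.n_proteins))
    for p in range(config.n_proteins):
        pid = f"syn{p + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aa, size=length, p=bg).tolist()

        # candidate anchors eligible for promotion: edits must fit inside the
        # sequence (1-based position pos needs pos+min_off >= 1, pos+max_off <= length)
        eligible = [
            i + 1
            for i, res in enumerate(seq)
            if res in anchors and i + 1 + min_off >= 1 and i + 1 + max_off <= length
        ]
        promoted: list[int] = []
        occupied: list[tuple[int, int]] = []
        order = rng.permutation(len(eligible))
        for idx in order:
            pos = eligible[idx]
            if rng.random() >= config.positive_rate:
                continue
            span = (pos + min_off, pos + max_off)
            if any(span[0] <= hi_ and lo_ <= span[1] for lo_, hi_ in occupied):
                continue
            promoted.append(pos)
            occupied.append(span)
            _install_site(seq, pos, config, rng, bg)

        sequence = "".join(seq)
        protein = ProteinRecord(pid, sequence)
        proteins.append(protein)
        promoted.sort()
        annotations.extend(
            GlycositeAnnotation(pid, pos, config.glyco_type) for pos in promoted
        )
        all_candidates = candidate_sites(protein, config.glyco_type)
        manifest_proteins[pid] = {
            "length": length,
            "planted_sites": promoted,
            "candidate_sites": all_candidates,
            "accidental_candidates": sorted(set(all_candidates) - set(promoted)),
        }

    manifest = {
        "glyco_type": config.glyco_type.value,
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "positive_rate": config.positive_rate,
        "signal": [[s.offset, s.residue, s.excess] for s in config.signal],
        "proteins": manifest_proteins,
    }
    return SyntheticDataset(tuple(proteins), tuple(annotations), manifest)


def _install_site(
    seq: list[str],
    pos: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    bg: np.ndarray,
) -> None:
    """Edit `seq` in place around the (1-based) anchor at `pos`."""
    aa = list(AA_ALPHABET)
    # positional signal first; sequon constraints re-imposed afterwards
    for s in config.signal:
        i = pos - 1 + s.offset
        target = bg[aa.index(s.residue)] + s.excess
        if rng.random() < target:
            seq[i] = s.residue
        else:
            probs = bg.copy()
            probs[aa.index(s.residue)] = 0.0
            probs /= probs.sum()
            seq[i] = str(rng.choice(aa, p=probs))
    if config.glyco_type is GlycoType.N:
        # Asn-X-Ser/Thr with X != Pro
        if seq[pos] == "P":
            probs = bg.copy()
            probs[aa.index("P")] = 0.0
            probs /= probs.sum()
            seq[pos] = str(rng.choice(aa, p=probs))
        if seq[pos + 1] not in "ST":
            s_bg, t_bg = bg[aa.index("S")], bg[aa.index("T")]
            p_ser = s_bg / (s_bg + t_bg) if s_bg + t_bg > 0 else 0.5
            seq[pos + 1] = "S" if rng.random() < p_ser else "T"
    elif config.glyco_type is GlycoType.C:
        # W-X-X-[W/C/F]
        if seq[pos + 2] not in "WCF":
            seq[pos + 2] = str(rng.choice(["W", "C", "F"]))
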