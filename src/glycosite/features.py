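"""Numeric encodings of sequence windows and the provider contracts they use.

Encoders
--------
* BPP — binary profile: each window residue as a 21-dimensional one-hot
  vector (20 amino acids + dummy X, alphabetical with X last); 21*L total.
* CPP — composition profile: fraction of each of the 20 amino acids in the
  window, pad symbols excluded from the denominator; 20 total.
* PPP — evolutionary profile: 20 per-position substitution propensities from
  a pluggable profile provider, squashed to (0,1) with the logistic function;
  pad positions contribute rows of zeros (distinguishable from logistic(0) =
  0.5); 20*L total.
* SS  — three-state secondary-structure probabilities (coil, helix, strand)
  per position; 3*L total.
* ASA — predicted relative surface accessibility per position in [0,1];
  L total.

Providers are injected so the package never shells out to PSI-BLAST, PSIPRED
or an accessibility predictor: file adapters parse those tools' standard
output formats, and deterministic offline providers (substitution-matrix
profile; propensity-scale structure) make the whole pipeline runnable from
sequence alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from glycosite.core import AA_ALPHABET, ALPHABET, PAD_SYMBOL, ProteinRecord
from glycosite.patterns import Pattern

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class FeatureVector:
    """An ordered real vector plus the schema naming the encoder combination."""

    values: np.ndarray
    schema: str
    source: tuple[str, int] | None = None  # (protein_id, center_position)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


class ProfileProvider(Protocol):
    """Per-residue evolutionary profile: 20 substitution scores per position."""

    def profile(self, protein_id: str) -> np.ndarray: ...  # (length, 20)

    def protein_length(self, protein_id: str) -> int: ...


class StructureProvider(Protocol):
    """Per-residue secondary-structure probabilities and surface accessibility."""

    asa_max: float

    def ss_probabilities(self, protein_id: str) -> np.ndarray: ...  # (length, 3) C,H,E

    def asa(self, protein_id: str) -> np.ndarray: ...  # (length,)

    def protein_length(self, protein_id: str) -> int: ...


def encode_bpp(pattern: Pattern | str) -> FeatureVector:
    """One-hot encode a window: 21 dimensions per residue, X last."""
    window, source = _window_of(pattern)
    L = len(window)
    values = np.zeros((L, 21))
    for i, symbol in enumerate(window):
        try:
            values[i, _AA_INDEX[symbol]] = 1.0
        except KeyError:
            raise ValueError(f"symbol {symbol!r} outside the 21-letter alphabet")
    return FeatureVector(values.ravel(), f"BPP{L}", source)


def encode_cpp(pattern: Pattern | str) -> FeatureVector:
    """Amino-acid composition of the window; pads excluded from the denominator."""
    window, source = _window_of(pattern)
    counts = np.zeros(20)
    n_real = 0
    for symbol in window:
        if symbol == PAD_SYMBOL:
            continue
        counts[_AA_INDEX[symbol]] += 1
        n_real += 1
    if n_real == 0:
        raise ValueError("window contains only pad symbols")
    return FeatureVector(counts / n_real, "CPP", source)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _window_positions(pattern: Pattern, length: int) -> list[int | None]:
    """Protein position per window slot (1-based), None for pad slots."""
    flank = len(pattern.window) // 2
    positions: list[int | None] = []
    for offset in range(-flank, flank + 1):
        pos = pattern.center_position + offset
        positions.append(pos if 1 <= pos <= length else None)
    return positions


def encode_ppp(pattern: Pattern, provider: ProfileProvider) -> FeatureVector:
    """Logistic-squashed profile scores per window position; pads are zero rows."""
    profile = provider.profile(pattern.protein_id)
    L = len(pattern.window)
    rows = np.zeros((L, 20))
    for i, pos in enumerate(_window_positions(pattern, len(profile))):
        if pos is not None:
            rows[i] = _logistic(profile[pos - 1])
    return FeatureVector(rows.ravel(), f"PPP{L}", (pattern.protein_id, pattern.center_position))


def encode_ss(pattern: Pattern, provider: StructureProvider) -> FeatureVector:
    """Coil/helix/strand probability triplet per window position; pads are zeros."""
    probs = provider.ss_probabilities(pattern.protein_id)
    L = len(pattern.window)
    rows = np.zeros((L, 3))
    for i, pos in enumerate(_window_positions(pattern, len(probs))):
        if pos is not None:
            rows[i] = probs[pos - 1]
    return FeatureVector(rows.ravel(), f"SS{L}", (pattern.protein_id, pattern.center_position))


def encode_asa(pattern: Pattern, provider: StructureProvider) -> FeatureVector:
    """Relative surface accessibility per window position in [0,1]; pads are 0."""
    asa = np.asarray(provider.asa(pattern.protein_id), dtype=float) / provider.asa_max
    L = len(pattern.window)
    values = np.zeros(L)
    for i, pos in enumerate(_window_positions(pattern, len(asa))):
        if pos is not None:
            values[i] = asa[pos - 1]
    return FeatureVector(values, f"ASA{L}", (pattern.protein_id, pattern.center_position))


def combine(encodings: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate encodings of the same pattern; schema records the order."""
    if not encodings:
        raise ValueError("nothing to combine")
    if len(encodings) == 1:
        return encodings[0]
    sources = {e.source for e in encodings if e.source is not None}
    if len(sources) > 1:
        raise ValueError(f"cannot combine encodings of different patterns: {sources}")
    return FeatureVector(
        np.concatenate([e.values for e in encodings]),
        "+".join(e.schema for e in encodings),
        next(iter(sources)) if sources else None,
    )


def _window_of(pattern: Pattern | str) -> tuple[str, tuple[str, int] | None]:
    if isinstance(pattern, Pattern):
        return pattern.window, (pattern.protein_id, pattern.center_position)
    return pattern, None


# ---------------------------------------------------------------------------
# Encoder assembly

ENCODER_NAMES = ("BPP", "CPP", "PPP", "SS", "ASA")


def make_encoder(
    features: Sequence[str],
    profile_provider: ProfileProvider | None = None,
    structure_provider: StructureProvider | None = None,
) -> Callable[[Pattern], FeatureVector]:
    """Build a pattern -> FeatureVector function for a feature combination.

    ``features`` is an ordered list drawn from BPP, CPP, PPP, SS, ASA. The
    profile provider is required for PPP, the structure provider for SS/ASA.
    """
    features = [f.upper() for f in features]
    unknown = set(features) - set(ENCODER_NAMES)
    if unknown:
        raise ValueError(f"unknown encoders {sorted(unknown)}; choose from {ENCODER_NAMES}")
    if "PPP" in features and profile_provider is None:
        raise ValueError("PPP requires a profile provider")
    if ({"SS", "ASA"} & set(features)) and structure_provider is None:
        raise ValueError("SS/ASA require a structure provider")

    def encode(pattern: Pattern) -> FeatureVector:
        parts = []
        for name in features:
            if name == "BPP":
                parts.append(encode_bpp(pattern))
            elif name == "CPP":
                parts.append(encode_cpp(pattern))
            elif name == "PPP":
                parts.append(encode_ppp(pattern, profile_provider))
            elif name == "SS":
                parts.append(encode_ss(pattern, structure_provider))
            elif name == "ASA":
                parts.append(encode_asa(pattern, structure_provider))
        return combine(parts)

    return encode


def encode_dataset(
    patterns: Sequence[Pattern],
    encoder: Callable[[Pattern], FeatureVector],
) -> tuple[np.ndarray, np.ndarray, str]:
    """Encode patterns into (X, y, schema); y is 1 for positive, 0 for negative."""
    if not patterns:
        raise ValueError("no patterns to encode")
    vectors = [encoder(p) for p in patterns]
    schemas = {v.schema for v in vectors}
    if len(schemas) > 1:
        raise ValueError(f"inconsistent schemas {sorted(schemas)}")
    X = np.vstack([v.values for v in vectors])
    y = np.array([1 if p.is_positive else 0 for p in patterns])
    return X, y, schemas.pop()


# ---------------------------------------------------------------------------
# Deterministic offline providers (no external binaries required)


class SubstitutionMatrixProfileProvider:
    """Profile provider backed by a substitution matrix (default BLOSUM62).

    Each residue's profile row is its 20 substitution scores in alphabet
    order — a sequence-only stand-in for an alignment-derived position
    weight matrix, adequate for pipelines where no search profile exists.
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord] | Mapping[str, str],
        matrix_name: str = "BLOSUM62",
    ) -> None:
        if isinstance(proteins, Mapping):
            self._sequences = dict(proteins)
        else:
            self._sequences = {p.id: p.sequence for p in proteins}
        matrix = substitution_matrices.load(matrix_name)
        self._rows = {
            res: np.array([matrix[res][aa] for aa in AA_ALPHABET], dtype=float)
            for res in AA_ALPHABET + PAD_SYMBOL
        }

    def protein_length(self, protein_id: str) -> int:
        return len(self._sequence(protein_id))

    def profile(self, protein_id: str) -> np.ndarray:
        seq = self._sequence(protein_id)
        return np.vstack([self._rows[res] for res in seq])

    def _sequence(self, protein_id: str) -> str:
        try:
            return self._sequences[protein_id]
        except KeyError:
            raise KeyError(f"no sequence registered for protein {protein_id!r}")


#: Chou–Fasman conformational propensities (helix P_alpha, strand P_beta).
_HELIX_PROPENSITY = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11, "E": 1.51,
    "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13,
    "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
_STRAND_PROPENSITY = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10, "E": 0.37,
    "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38,
    "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}
#: Kyte–Doolittle hydropathy, used (inverted) as a surface-exposure proxy.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class PropensityStructureProvider:
    """Deterministic structure provider from published residue scales.

    Secondary-structure probabilities come from Chou–Fasman helix/strand
    propensities with a unit coil propensity, normalised per residue; the
    accessibility proxy is inverted, rescaled Kyte–Doolittle hydropathy in
    [0,1] (hydrophilic residues score as exposed). Values are coarse
    per-residue priors, not structure predictions.
    """

    asa_max = 1.0

    def __init__(self, proteins: Sequence[ProteinRecord] | Mapping[str, str]) -> None:
        if isinstance(proteins, Mapping):
            self._sequences = dict(proteins)
        else:
            self._sequences = {p.id: p.sequence for p in proteins}

    def protein_length(self, protein_id: str) -> int:
        return len(self._sequence(protein_id))

    def ss_probabilities(self, protein_id: str) -> np.ndarray:
        seq = self._sequence(protein_id)
        rows = np.empty((len(seq), 3))
        for i, res in enumerate(seq):
            helix = _HELIX_PROPENSITY.get(res, 1.0)
            strand = _STRAND_PROPENSITY.get(res, 1.0)
            coil = 1.0
            total = coil + helix + strand
            rows[i] = (coil / total, helix / total, strand / total)
        return rows

    def asa(self, protein_id: str) -> np.ndarray:
        seq = self._sequence(protein_id)
        return np.array([(4.5 - _HYDROPATHY.get(res, 0.0)) / 9.0 for res in seq])

    def _sequence(self, protein_id: str) -> str:
        try:
            return self._sequences[protein_id]
        except KeyError:
            raise KeyError(f"no sequence registered for protein {protein_id!r}")


# ---------------------------------------------------------------------------
# File-format adapters for external predictor output


class PssmFileProvider:
    """Reads PSI-BLAST ASCII position-specific scoring matrices.

    Expects the standard ``-out_ascii_pssm`` layout: two header lines, then
    one row per residue starting with the position index and residue letter
    followed by at least 20 integer log-odds columns (the first 20 are used,
    reordered from the file's column header into alphabet order).
    """

    def __init__(self, paths: Mapping[str, str | Path]) -> None:
        self._paths = {pid: Path(p) for pid, p in paths.items()}
        self._cache: dict[str, np.ndarray] = {}

    def protein_length(self, protein_id: str) -> int:
        return len(self.profile(protein_id))

    def profile(self, protein_id: str) -> np.ndarray:
        if protein_id not in self._cache:
            self._cache[protein_id] = self._parse(self._paths[protein_id])
        return self._cache[protein_id]

    @staticmethod
    def _parse(path: Path) -> np.ndarray:
        rows = []
        order: list[str] | None = None
        for line in path.read_text().splitlines():
            parts = line.split()
            if order is None:
                # column header: 40 letters (log-odds block then percentages)
                if len(parts) >= 20 and all(p in AA_ALPHABET for p in parts[:20]):
                    order = parts[:20]
                continue
            if len(parts) >= 22 and parts[0].isdigit():
                scores = [float(v) for v in parts[2:22]]
                by_letter = dict(zip(order, scores))
                rows.append([by_letter[aa] for aa in AA_ALPHABET])
        if not rows:
            raise ValueError(f"{path}: no PSSM rows found")
        return np.array(rows)


class Ss2FileProvider:
    """Reads PSIPRED ``.ss2`` files (idx, residue, state, pC, pH, pE).

    Also serves ASA when paired ASA tables are supplied; otherwise
    :meth:`asa` raises.
    """

    asa_max = 100.0

    def __init__(
        self,
        ss2_paths: Mapping[str, str | Path],
        asa_paths: Mapping[str, str | Path] | None = None,
    ) -> None:
        self._ss2 = {pid: Path(p) for pid, p in ss2_paths.items()}
        self._asa = {pid: Path(p) for pid, p in (asa_paths or {}).items()}

    def protein_length(self, protein_id: str) -> int:
        return len(self.ss_probabilities(protein_id))

    def ss_probabilities(self, protein_id: str) -> np.ndarray:
        rows = []
        for line in self._ss2[protein_id].read_text().splitlines():
            parts = line.split()
            if len(parts) == 6 and parts[0].isdigit():
                rows.append([float(parts[3]), float(parts[4]), float(parts[5])])
        if not rows:
            raise ValueError(f"{self._ss2[protein_id]}: no .ss2 rows found")
        return np.array(rows)

    def asa(self, protein_id: str) -> np.ndarray:
        if protein_id not in self._asa:
            raise KeyError(f"no ASA table registered for protein {protein_id!r}")
        return AsaFileProvider({protein_id: self._asa[protein_id]}).asa(protein_id)


class AsaFileProvider:
    """Reads tabular per-residue accessibility files (idx, residue, value)."""

    def __init__(self, paths: Mapping[str, str | Path], asa_max: float = 100.0) -> None:
        self._paths = {pid: Path(p) for pid, p in paths.items()}
        self.asa_max = asa_max

    def protein_length(self, protein_id: str) -> int:
        return len(self.asa(protein_id))

    def asa(self, protein_id: str) -> np.ndarray:
        values = []
        for line in self._paths[protein_id].read_text().splitlines():
            parts = line.split()
            if len(parts) >= 3 and parts[0].isdigit():
                values.append(float(parts[2]))
        if not values:
            raise ValueError(f"{self._paths[protein_id]}: no ASA rows found")
        return np.array(values)

    def ss_probabilities(self, protein_id: str) -> np.ndarray:
        raise KeyError("ASA-only provider has no secondary-structure data")
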