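"""Redundancy reduction, train/held-out splitting, and class balancing.

Two levels of redundancy reduction are provided, mirroring the two dataset
tiers used for glycosite model building:

* protein level — greedy incremental clustering of full-length sequences by
  global-alignment identity (CD-HIT style, exhaustive comparisons instead of
  the k-mer prefilter), keeping one representative per cluster;
* pattern level — greedy filtering of fixed-length windows so that no two
  kept windows exceed a percent-identity cutoff, positives first so that
  negatives near-identical to a kept positive are removed (sharper class
  divide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from glycosite.core import ProteinRecord
from glycosite.patterns import Pattern

logger = logging.getLogger(__name__)

#: Pattern-level cutoffs used in the redundancy ladder.
LADDER_CUTOFFS = (100.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0)


@dataclass(frozen=True)
class SimilarityCutoff:
    percent: float

    def __post_init__(self) -> None:
        if not 0 < self.percent <= 100:
            raise ValueError(f"cutoff must be in (0, 100], got {self.percent}")


@dataclass(frozen=True)
class SplitSpec:
    """Train/held-out split specification; default 4:1 train:independent."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


def pattern_identity(a: str, b: str) -> float:
    """Ungapped position-wise percent identity between two equal-length windows.

    Windows are pre-aligned by their centre residue, so no alignment is
    needed; the dummy residue X matches only X.
    """
    if len(a) != len(b):
        raise ValueError(f"window lengths differ: {len(a)} vs {len(b)}")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def _window_matrix(windows: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(
        len(windows), -1
    )


def prune_patterns(
    patterns: Sequence[Pattern], cutoff: float | SimilarityCutoff
) -> list[Pattern]:
    """Greedy pattern-level redundancy reduction.

    Iterates positives first (in input order), then negatives; a pattern is
    kept iff its identity to every already-kept pattern is <= cutoff
    ("more similar than the cutoff" is strict). Exact duplicate windows are
    always removed, so the 100% rung of the redundancy ladder deduplicates.
    Output preserves input order within each class.
    """
    if isinstance(cutoff, SimilarityCutoff):
        cutoff = cutoff.percent
    else:
        SimilarityCutoff(cutoff)  # range check
    if not patterns:
        return []
    lengths = {len(p.window) for p in patterns}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    (L,) = lengths
    ordered = [p for p in patterns if p.is_positive] + [
        p for p in patterns if not p.is_positive
    ]
    max_matches = cutoff * L / 100.0
    kept: list[Pattern] = []
    kept_rows = np.empty((len(ordered), L), dtype=np.uint8)
    n_kept = 0
    for p in ordered:
        row = np.frombuffer(p.window.encode("ascii"), dtype=np.uint8)
        if n_kept:
            best = (kept_rows[:n_kept] == row).sum(axis=1).max()
            if best > max_matches or best == L:
                continue
        kept_rows[n_kept] = row
        n_kept += 1
        kept.append(p)
    return kept


def _global_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    """Percent identity from a global alignment, normalised by the shorter sequence."""
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / min(len(a), len(b))


def make_protein_aligner() -> Align.PairwiseAligner:
    """Global aligner with BLOSUM62, gap open 10, gap extend 1."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def cluster_proteins(
    proteins: Sequence[ProteinRecord], cutoff: float
) -> list[ProteinRecord]:
    """Greedy incremental clustering; returns one representative per cluster.

    Proteins are sorted by length descending (ties keep input order); each
    protein joins the first representative whose global-alignment identity
    exceeds the cutoff, else founds a new cluster. Identity is the number of
    aligned identical residues over the length of the shorter sequence.
    """
    SimilarityCutoff(cutoff)
    if not proteins:
        raise ValueError("no proteins to cluster")
    aligner = make_protein_aligner()
    ordered = sorted(proteins, key=lambda p: -len(p.sequence))
    representatives: list[ProteinRecord] = []
    for protein in ordered:
        if not any(
            _global_identity(aligner, rep.sequence, protein.sequence) > cutoff
            for rep in representatives
        ):
            representatives.append(protein)
    return representatives


def split_patterns(
    patterns: Sequence[Pattern], spec: SplitSpec = SplitSpec()
) -> tuple[list[Pattern], list[Pattern]]:
    """Seeded random split into (train, independent) sets, stratified by label.

    Positives and negatives are split separately at the same fraction so both
    sets keep the class ratio; within each output the original input order is
    preserved. Train size per class is round(train_fraction * n).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(patterns)
    if n < 5:
        logger.warning("fewer than 5 patterns: independent set may be empty")
    train_idx: set[int] = set()
    for positive in (True, False):
        idx = [i for i, p in enumerate(patterns) if p.is_positive == positive]
        if not idx:
            continue
        n_train = round(spec.train_fraction * len(idx))
        chosen = rng.permutation(len(idx))[:n_train]
        train_idx.update(idx[i] for i in chosen)
    train = [p for i, p in enumerate(patterns) if i in train_idx]
    independent = [p for i, p in enumerate(patterns) if i not in train_idx]
    return train, independent


def balance(patterns: Sequence[Pattern], seed: int = 0) -> list[Pattern]:
    """All positives plus an equal-sized seeded subsample of negatives.

    If there are fewer negatives than positives, all negatives are kept with
    a warning. Output preserves input order.
    """
    positives = [p for p in patterns if p.is_positive]
    negatives = [p for p in patterns if not p.is_positive]
    if not positives or not negatives:
        raise ValueError("balance requires at least one pattern of each class")
    if len(negatives) < len(positives):
        logger.warning(
            "only %d negatives for %d positives; keeping all negatives",
            len(negatives), len(positives),
        )
        chosen = set(range(len(negatives)))
    else:
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(len(negatives), size=len(positives), replace=False).tolist())
    sampled = {id(negatives[i]) for i in chosen}
    return [p for p in patterns if p.is_positive or id(p) in sampled]
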