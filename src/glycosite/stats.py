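"""Descriptive statistics of glycosites: positional residue frequencies
around the site (sequence-logo style) and the spread of sites across
normalised protein length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from glycosite.core import ALPHABET, GlycositeAnnotation, ProteinRecord
from glycosite.patterns import Pattern


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position symbol frequencies relative to the site (offset 0 = site).

    The dummy residue X is a first-class symbol so terminal-window padding is
    visible instead of being silently renormalised away.
    """

    table: pd.DataFrame  # index: offsets -(L-1)/2..+(L-1)/2; columns: 21 symbols

    def frequency(self, offset: int, symbol: str) -> float:
        return float(self.table.loc[offset, symbol])


@dataclass(frozen=True)
class SpreadHistogram:
    """Counts of sites per normalised protein-length bin."""

    counts: np.ndarray
    n_bins: int
    total_sites: int

    def to_frame(self) -> pd.DataFrame:
        edges = [
            (100.0 * b / self.n_bins, 100.0 * (b + 1) / self.n_bins)
            for b in range(self.n_bins)
        ]
        return pd.DataFrame(
            {
                "bin": range(1, self.n_bins + 1),
                "start_percent": [lo for lo, _ in edges],
                "end_percent": [hi for _, hi in edges],
                "count": self.counts,
            }
        )


def positional_frequency(patterns: Sequence[Pattern]) -> FrequencyMatrix:
    """Symbol frequency at each window offset, from positive patterns.

    Every column (offset) sums to exactly 1; pads count as X.
    """
    if not patterns:
        raise ValueError("no patterns given")
    lengths = {len(p.window) for p in patterns}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    (L,) = lengths
    flank = L // 2
    counts = np.zeros((L, len(ALPHABET)))
    index = {s: i for i, s in enumerate(ALPHABET)}
    for p in patterns:
        for i, symbol in enumerate(p.window):
            counts[i, index[symbol]] += 1
    freqs = counts / len(patterns)
    table = pd.DataFrame(
        freqs, index=range(-flank, flank + 1), columns=list(ALPHABET)
    )
    return FrequencyMatrix(table)


def spread_histogram(
    annotations: Sequence[GlycositeAnnotation],
    proteins: Sequence[ProteinRecord],
    n_bins: int = 20,
) -> SpreadHistogram:
    """Histogram of sites over relative sequence position (default 5% bins).

    Relative position r = position/length lies in (0, 1]; bin b covers
    ((b-1)/n_bins, b/n_bins], so a site at the last residue lands in the last
    bin and none is ever dropped.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    lengths = {p.id: len(p) for p in proteins}
    counts = np.zeros(n_bins, dtype=int)
    for ann in annotations:
        if ann.protein_id not in lengths:
            raise KeyError(f"annotation references unknown protein {ann.protein_id!r}")
        r = ann.position / lengths[ann.protein_id]
        if not 0 < r <= 1:
            raise ValueError(
                f"{ann.protein_id}: position {ann.position} outside protein length"
            )
        counts[math.ceil(r * n_bins) - 1] += 1
    return SpreadHistogram(counts=counts, n_bins=n_bins, total_sites=len(annotations))
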