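import numpy as np
import pytest

from glycosite.core import GlycoType, ProteinRecord, validate_annotations
from glycosite.patterns import PatternConfig, build_patterns
from glycosite.simulate import SignalSpec, SyntheticConfig, generate


@pytest.fixture
def toy_proteins():
    return [
        ProteinRecord("p1", "NAST"),
        ProteinRecord("p2", "WAAWAAC"),
        ProteinRecord("p3", "MNNSSAQT"),
    ]


def patterns_from_dataset(dataset, glyco_type, window_length=21):
    """All labelled patterns from a synthetic dataset's annotated proteins."""
    valid, rejected = validate_annotations(dataset.proteins, dataset.annotations)
    assert not rejected
    by_protein = {}
    for ann in valid:
        by_protein.setdefault(ann.protein_id, set()).add(ann.position)
    config = PatternConfig(window_length=window_length)
    patterns = []
    for protein in dataset.proteins:
        if protein.id in by_protein:
            patterns.extend(
                build_patterns(protein, by_protein[protein.id], glyco_type, config)
            )
    return patterns


@pytest.fixture(scope="session")
def signal_dataset():
    """N-linked synthetic dataset with strong positional signal around sites."""
    config = SyntheticConfig(
        n_proteins=125,
        glyco_type=GlycoType.N,
        positive_rate=0.12,
        signal=(
            SignalSpec(-3, "P", 0.5),
            SignalSpec(-1, "G", 0.5),
            SignalSpec(3, "A", 0.5),
        ),
        seed=11,
    )
    return generate(config)


@pytest.fixture(scope="session")
def signal_patterns(signal_dataset):
    return patterns_from_dataset(signal_dataset, GlycoType.N)


def subsample_imbalanced(patterns, n_pos, n_neg, seed):
    """Seeded subsample with exact class counts (positives first in output)."""
    rng = np.random.default_rng(seed)
    pos = [p for p in patterns if p.is_positive]
    neg = [p for p in patterns if not p.is_positive]
    assert len(pos) >= n_pos and len(neg) >= n_neg, (len(pos), len(neg))
    pos = [pos[i] for i in rng.permutation(len(pos))[:n_pos]]
    neg = [neg[i] for i in rng.permutation(len(neg))[:n_neg]]
    return pos + neg
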