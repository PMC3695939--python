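import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from glycosite.core import AA_ALPHABET, ProteinRecord
from glycosite.patterns import NEGATIVE, POSITIVE, GlycoType, Pattern
from glycosite.redundancy import (
    SimilarityCutoff,
    SplitSpec,
    balance,
    cluster_proteins,
    pattern_identity,
    prune_patterns,
    split_patterns,
)

ALPHABET22 = AA_ALPHABET  # residue pool for random windows


def random_pattern(rng, L=9, p_positive=0.5):
    flank = L // 2
    window = "".join(rng.choice(list(AA_ALPHABET), size=L))
    window = window[:flank] + "N" + window[flank + 1 :]
    label = POSITIVE if rng.random() < p_positive else NEGATIVE
    return Pattern("p", int(rng.integers(1, 1000)), window, GlycoType.N, label)


# --- independent oracles -----------------------------------------------------

def oracle_prune(patterns, cutoff):
    """Plain-python greedy reference: positives first, pairwise scan."""
    ordered = [p for p in patterns if p.label == POSITIVE] + [
        p for p in patterns if p.label == NEGATIVE
    ]
    kept = []
    for p in ordered:
        ok = True
        for q in kept:
            matches = sum(a == b for a, b in zip(p.window, q.window))
            identity = 100.0 * matches / len(p.window)
            if identity > cutoff or identity == 100.0:
                ok = False
                break
        if ok:
            kept.append(p)
    return kept


def oracle_cluster(proteins, cutoff):
    """Greedy clustering reference with its own alignment identity."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0

    def identity(a, b):
        alignment = aligner.align(a, b)[0]
        sa, sb = str(alignment[0]), str(alignment[1])
        matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
        return 100.0 * matches / min(len(a), len(b))

    ordered = sorted(proteins, key=lambda p: -len(p.sequence))
    reps = []
    for protein in ordered:
        if all(identity(r.sequence, protein.sequence) <= cutoff for r in reps):
            reps.append(protein)
    return reps


# --- tests -------------------------------------------------------------------

class TestPatternIdentity:
    def test_identical_and_disjoint(self):
        assert pattern_identity("NASTG", "NASTG") == 100.0
        assert pattern_identity("AAAAA", "CCCCC") == 0.0

    def test_thirteen_of_21(self):
        a = "A" * 21
        b = "A" * 13 + "C" * 8
        assert pattern_identity(a, b) == pytest.approx(61.90, abs=0.005)

    def test_pad_matches_only_pad(self):
        assert pattern_identity("XXA", "XXC") == pytest.approx(100 * 2 / 3)
        assert pattern_identity("XAA", "AAA") == pytest.approx(100 * 2 / 3)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            pattern_identity("AA", "AAA")


class TestPrunePatterns:
    def test_exact_duplicates_removed_at_100(self):
        p = Pattern("p", 1, "XXNAS", GlycoType.N, POSITIVE)
        q = Pattern("q", 2, "XXNAS", GlycoType.N, POSITIVE)
        r = Pattern("r", 3, "XANAS", GlycoType.N, POSITIVE)
        kept = prune_patterns([p, q, r], 100)
        assert kept == [p, r]  # only the exact duplicate window dropped

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(400):
            n = int(rng.integers(1, 21))
            patterns = [random_pattern(rng, L=7) for _ in range(n)]
            cutoff = float(rng.choice([100, 90, 80, 70, 60, 50, 40]))
            assert prune_patterns(patterns, cutoff) == oracle_prune(patterns, cutoff)

    def test_idempotent_and_pairwise_bound(self):
        rng = np.random.default_rng(7)
        patterns = [random_pattern(rng, L=9) for _ in range(40)]
        kept = prune_patterns(patterns, 60)
        assert prune_patterns(kept, 60) == kept
        for i, p in enumerate(kept):
            for q in kept[i + 1 :]:
                assert pattern_identity(p.window, q.window) <= 60

    def test_ladder_counts_monotone(self):
        rng = np.random.default_rng(3)
        patterns = [random_pattern(rng, L=9) for _ in range(120)]
        counts = [len(prune_patterns(patterns, c)) for c in (100, 90, 80, 70, 60, 50, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_positives_shield_similar_negatives(self):
        pos = Pattern("p", 1, "AANAA", GlycoType.N, POSITIVE)
        neg = Pattern("q", 9, "AANAA", GlycoType.N, NEGATIVE)
        assert prune_patterns([neg, pos], 100) == [pos]

    def test_cutoff_range_validated(self):
        with pytest.raises(ValueError):
            SimilarityCutoff(0)
        with pytest.raises(ValueError):
            prune_patterns([], 101)


class TestClusterProteins:
    def test_single_and_identical(self):
        a = ProteinRecord("a", "NASTGAKLMV")
        b = ProteinRecord("b", "NASTGAKLMV")
        assert cluster_proteins([a], 40) == [a]
        assert cluster_proteins([a, b], 40) == [a]

    def test_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            proteins = []
            base = "".join(rng.choice(list(AA_ALPHABET), size=30))
            for i in range(n):
                if rng.random() < 0.5:
                    # mutated copy of the base: some clusters form
                    seq = list(base)
                    for j in rng.choice(30, size=int(rng.integers(0, 15)), replace=False):
                        seq[j] = str(rng.choice(list(AA_ALPHABET)))
                    proteins.append(ProteinRecord(f"p{i}", "".join(seq)))
                else:
                    length = int(rng.integers(10, 35))
                    proteins.append(
                        ProteinRecord(f"p{i}", "".join(rng.choice(list(AA_ALPHABET), size=length)))
                    )
            cutoff = float(rng.choice([40, 60, 80]))
            ours = [p.id for p in cluster_proteins(proteins, cutoff)]
            ref = [p.id for p in oracle_cluster(proteins, cutoff)]
            assert ours == ref


class TestSplitPatterns:
    def make(self, n_pos, n_neg):
        rng = np.random.default_rng(0)
        return [random_pattern(rng, p_positive=1.0) for _ in range(n_pos)] + [
            random_pattern(rng, p_positive=0.0) for _ in range(n_neg)
        ]

    def test_ratio_and_stratification(self):
        patterns = self.make(10, 40)
        train, independent = split_patterns(patterns, SplitSpec(seed=1))
        assert len(train) == 40 and len(independent) == 10
        assert sum(p.is_positive for p in train) == 8
        assert sum(p.is_positive for p in independent) == 2

    def test_deterministic_and_partition(self):
        patterns = self.make(7, 23)
        a = split_patterns(patterns, SplitSpec(seed=9))
        b = split_patterns(patterns, SplitSpec(seed=9))
        assert a == b
        train, independent = a
        combined = sorted(train + independent, key=id)
        assert combined == sorted(patterns, key=id)
        assert not ({id(p) for p in train} & {id(p) for p in independent})

    def test_tiny_input_warns(self, caplog):
        patterns = self.make(1, 2)
        split_patterns(patterns, SplitSpec(seed=0))
        assert any("fewer than 5" in r.message for r in caplog.records)


class TestBalance:
    def test_equal_counts(self):
        patterns = TestSplitPatterns().make(5, 100)
        balanced = balance(patterns, seed=0)
        assert len(balanced) == 10
        assert sum(p.is_positive for p in balanced) == 5

    def test_negative_shortage_keeps_all(self, caplog):
        patterns = TestSplitPatterns().make(5, 3)
        balanced = balance(patterns, seed=0)
        assert len(balanced) == 8
        assert any("keeping all negatives" in r.message for r in caplog.records)

    def test_deterministic(self):
        patterns = TestSplitPatterns().make(4, 50)
        assert balance(patterns, seed=3) == balance(patterns, seed=3)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            balance(TestSplitPatterns().make(5, 0), seed=0)
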