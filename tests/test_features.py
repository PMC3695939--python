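import numpy as np
import pytest
from hypothesis import given, strategies as st

from glycosite.core import AA_ALPHABET, GlycoType, ProteinRecord
from glycosite.patterns import POSITIVE, Pattern, PatternConfig, build_patterns
from glycosite.features import (
    AsaFileProvider,
    FeatureVector,
    PropensityStructureProvider,
    PssmFileProvider,
    Ss2FileProvider,
    SubstitutionMatrixProfileProvider,
    combine,
    encode_asa,
    encode_bpp,
    encode_cpp,
    encode_dataset,
    encode_ppp,
    encode_ss,
    make_encoder,
)

windows21 = st.text(alphabet=AA_ALPHABET, min_size=10, max_size=10).map(
    lambda flanks: flanks + "N" + flanks[::-1]
)


class ConstantProfileProvider:
    def __init__(self, length, value=0.0):
        self._length, self._value = length, value

    def protein_length(self, protein_id):
        return self._length

    def profile(self, protein_id):
        return np.full((self._length, 20), self._value)


class ConstantStructureProvider:
    asa_max = 100.0

    def __init__(self, length, ss=(1 / 3, 1 / 3, 1 / 3), asa=50.0):
        self._length, self._ss, self._asa = length, ss, asa

    def protein_length(self, protein_id):
        return self._length

    def ss_probabilities(self, protein_id):
        return np.tile(self._ss, (self._length, 1))

    def asa(self, protein_id):
        return np.full(self._length, self._asa)


class TestBPP:
    def test_single_residue_one_hot(self):
        # Ala is the first 21-dim unit vector, Cys the second
        vec = encode_bpp("A" * 21).values.reshape(21, 21)
        assert vec[0, 0] == 1 and vec[0].sum() == 1
        vec = encode_bpp("C" + "A" * 20).values.reshape(21, 21)
        assert vec[0, 1] == 1 and vec[0].sum() == 1
        vec = encode_bpp("X" + "A" * 20).values.reshape(21, 21)
        assert vec[0, 20] == 1  # dummy residue is the last dimension

    @given(window=windows21)
    def test_dimension_and_one_hot_conservation(self, window):
        vec = encode_bpp(window)
        assert len(vec) == 441
        assert vec.values.sum() == 21
        assert vec.schema == "BPP21"

    @given(a=windows21, b=windows21)
    def test_injective_on_windows(self, a, b):
        same = np.array_equal(encode_bpp(a).values, encode_bpp(b).values)
        assert same == (a == b)

    def test_invalid_symbol_errors(self):
        with pytest.raises(ValueError):
            encode_bpp("A" * 20 + "-")


class TestCPP:
    def test_uniform_window(self):
        vec = encode_cpp("AAAAA")
        assert vec.values[0] == 1.0 and vec.values[1:].sum() == 0
        assert vec.schema == "CPP"

    def test_pads_excluded_from_denominator(self):
        vec = encode_cpp("XXNAS")
        by_aa = dict(zip(AA_ALPHABET, vec.values))
        assert by_aa["N"] == by_aa["A"] == by_aa["S"] == pytest.approx(1 / 3)
        assert vec.values.sum() == pytest.approx(1.0)

    @given(window=windows21)
    def test_normalization(self, window):
        assert encode_cpp(window).values.sum() == pytest.approx(1.0)

    def test_all_pad_window_errors(self):
        with pytest.raises(ValueError):
            encode_cpp("XXXXX")


def interior_pattern(seq="ANAAANASTAAANAAAAAAAANA", center=6, L=5):
    protein = ProteinRecord("p", seq)
    patterns = build_patterns(protein, set(), GlycoType.N, PatternConfig(L))
    return next(p for p in patterns if p.center_position == center), protein


class TestPPP:
    def test_zero_scores_give_half(self):
        pattern, protein = interior_pattern()
        provider = ConstantProfileProvider(len(protein))
        vec = encode_ppp(pattern, provider)
        assert vec.schema == "PPP5"
        assert np.all(vec.values == 0.5)

    def test_pad_rows_are_zero(self):
        protein = ProteinRecord("q", "N")
        (pattern,) = build_patterns(protein, set(), GlycoType.N, PatternConfig(5))
        vec = encode_ppp(pattern, ConstantProfileProvider(1)).values.reshape(5, 20)
        assert np.all(vec[[0, 1, 3, 4]] == 0.0)
        assert np.all(vec[2] == 0.5)

    def test_large_scores_saturate_to_one(self):
        pattern, protein = interior_pattern()
        vec = encode_ppp(pattern, ConstantProfileProvider(len(protein), value=50.0))
        assert np.all(np.isclose(vec.values, 1.0))

    def test_substitution_matrix_provider_deterministic(self):
        pattern, protein = interior_pattern()
        provider = SubstitutionMatrixProfileProvider([protein])
        a = encode_ppp(pattern, provider)
        b = encode_ppp(pattern, provider)
        assert np.array_equal(a.values, b.values)
        assert provider.protein_length("p") == len(protein)

    def test_missing_protein_errors(self):
        pattern, protein = interior_pattern()
        with pytest.raises(KeyError):
            encode_ppp(pattern, SubstitutionMatrixProfileProvider([]))


class TestStructureChannels:
    def test_uniform_ss(self):
        pattern, protein = interior_pattern()
        vec = encode_ss(pattern, ConstantStructureProvider(len(protein)))
        assert vec.schema == "SS5" and len(vec) == 15
        assert np.all(np.isclose(vec.values, 1 / 3))

    def test_length_one_protein_only_middle_triplet(self):
        protein = ProteinRecord("q", "N")
        (pattern,) = build_patterns(protein, set(), GlycoType.N, PatternConfig(5))
        vec = encode_ss(pattern, ConstantStructureProvider(1)).values.reshape(5, 3)
        assert np.all(vec[[0, 1, 3, 4]] == 0)
        assert np.all(np.isclose(vec[2], 1 / 3))

    def test_constant_asa_scaled(self):
        pattern, protein = interior_pattern()
        vec = encode_asa(pattern, ConstantStructureProvider(len(protein), asa=25.0))
        assert vec.schema == "ASA5" and len(vec) == 5
        assert np.all(np.isclose(vec.values, 0.25))

    def test_propensity_provider_bounds(self):
        protein = ProteinRecord("p", AA_ALPHABET)
        provider = PropensityStructureProvider([protein])
        ss = provider.ss_probabilities("p")
        assert ss.shape == (20, 3)
        assert np.allclose(ss.sum(axis=1), 1.0)
        asa = provider.asa("p")
        assert np.all((0 <= asa) & (asa <= 1))


class TestCombine:
    def test_lengths_add_and_schema_records_order(self):
        pattern, protein = interior_pattern(L=21)
        provider = ConstantStructureProvider(len(protein))
        bpp, asa = encode_bpp(pattern), encode_asa(pattern, provider)
        both = combine([bpp, asa])
        assert len(both) == 441 + 21
        assert both.schema == "BPP21+ASA21"
        cpp = encode_cpp(pattern)
        assert len(combine([cpp, asa])) == 41  # composition + accessibility

    def test_identity_on_singleton(self):
        vec = encode_cpp("XXNAS")
        assert combine([vec]) is vec

    def test_mixed_pattern_inputs_error(self):
        a, _ = interior_pattern(center=6)
        b, _ = interior_pattern(center=13)
        with pytest.raises(ValueError):
            combine([encode_bpp(a), encode_bpp(b)])


class TestEncoderAssembly:
    def test_make_encoder_requires_providers(self):
        with pytest.raises(ValueError):
            make_encoder(["PPP"])
        with pytest.raises(ValueError):
            make_encoder(["ASA"])
        with pytest.raises(ValueError):
            make_encoder(["WOBBLE"])

    def test_encode_dataset_shapes(self):
        protein = ProteinRecord("p", "NASTANPSAN")
        patterns = build_patterns(protein, {1}, GlycoType.N, PatternConfig(5))
        X, y, schema = encode_dataset(patterns, make_encoder(["BPP", "CPP"]))
        assert X.shape == (len(patterns), 105 + 20)
        assert schema == "BPP5+CPP"
        assert y.tolist() == [1 if p.is_positive else 0 for p in patterns]


class TestFileProviders:
    def test_pssm_ascii_round_trip(self, tmp_path):
        header = "\nLast position-specific scoring matrix computed\n"
        letters = "A R N D C Q E G H I L K M F P S T W V Y"
        lines = [header, "   " + letters + "  " + letters]
        for i, res in enumerate("NAS", start=1):
            scores = [str(i * 10 + j) for j in range(20)]
            lines.append(f"{i} {res} " + " ".join(scores) + " " + " ".join(["0"] * 20) + " 1.0 1.0")
        path = tmp_path / "x.pssm"
        path.write_text("\n".join(lines))
        provider = PssmFileProvider({"p": path})
        profile = provider.profile("p")
        assert profile.shape == (3, 20)
        # file order A R N D ... reordered into alphabetical A C D E ...
        assert profile[0, 0] == 10  # A stays first
        assert profile[0, 1] == 14  # C is file column 5 (0-based 4)
        assert provider.protein_length("p") == 3

    def test_ss2_reader(self, tmp_path):
        path = tmp_path / "x.ss2"
        path.write_text(
            "# PSIPRED VFORMAT\n\n"
            "   1 N C   0.9 0.05 0.05\n"
            "   2 A H   0.1 0.8 0.1\n"
        )
        provider = Ss2FileProvider({"p": path})
        probs = provider.ss_probabilities("p")
        assert probs.shape == (2, 3)
        assert probs[0, 0] == 0.9 and probs[1, 1] == 0.8

    def test_asa_reader_and_scaling(self, tmp_path):
        path = tmp_path / "x.asa"
        path.write_text("1 N 55.0\n2 A 12.5\n")
        provider = AsaFileProvider({"p": path})
        assert provider.asa("p").tolist() == [55.0, 12.5]
        assert provider.asa_max == 100.0
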