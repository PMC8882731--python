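"""The six feature encoders: worked examples, invariants, and oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylvote.encoders import (
    DINUCLEOTIDE_CODEBOOK,
    encode_adnf,
    encode_amnf,
    encode_fused,
    encode_matrix,
    encode_onehot1,
    encode_onehot2,
    encode_pcp,
    get_encoder,
    tokenize,
)
from methylvote.property_tables import (
    PropertyTable,
    default_dinucleotide_table,
    default_trinucleotide_table,
    kmer_tokens,
    read_property_table,
    write_property_table,
)

from conftest import make_dataset, random_window

windows_st = st.text(alphabet="ACGTN", min_size=2, max_size=41)


class TestTokenize:
    @pytest.mark.parametrize("seq,k,expected", [
        ("ACGTNA", 2, ["AC", "CG", "GT", "TN", "NA"]),
        ("A", 1, ["A"]),
        ("ACGT", 3, ["ACG", "CGT"]),
    ])
    def test_overlapping_kmers(self, seq, k, expected):
        assert tokenize(seq, k) == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tokenize("A", 2)


class TestCodebook:
    def test_lexicographic_anchors(self):
        # the ordering fixed by the printed codebook rows
        assert DINUCLEOTIDE_CODEBOOK["AA"] == 0
        assert DINUCLEOTIDE_CODEBOOK["AC"] == 1
        assert DINUCLEOTIDE_CODEBOOK["AG"] == 2
        assert DINUCLEOTIDE_CODEBOOK["NT"] == 23
        assert DINUCLEOTIDE_CODEBOOK["NN"] == 24
        assert sorted(DINUCLEOTIDE_CODEBOOK.values()) == list(range(25))


class TestOneHot:
    def test_onehot1_worked_example(self):
        expected = [1, 0, 0, 0, 0,  0, 1, 0, 0, 0,  0, 0, 1, 0, 0,
                    0, 0, 0, 1, 0,  0, 0, 0, 0, 1,  1, 0, 0, 0, 0]
        assert encode_onehot1("ACGTNA").tolist() == expected

    @pytest.mark.parametrize("seq,expected", [
        ("A", [1, 0, 0, 0, 0]),
        ("NN", [0, 0, 0, 0, 1, 0, 0, 0, 0, 1]),
    ])
    def test_onehot1_small(self, seq, expected):
        assert encode_onehot1(seq).tolist() == expected

    def test_onehot2_dimensions(self, rng):
        assert encode_onehot2("ACGTNA").shape == (125,)
        v = encode_onehot2(random_window(rng, 41))
        assert v.shape == (1000,)
        assert v.sum() == 40

    def test_onehot2_aa_single_bit(self):
        v = encode_onehot2("AA")
        assert v[0] == 1 and v.sum() == 1

    @given(windows_st)
    @settings(max_examples=150, derandomize=True)
    def test_row_sum_property(self, seq):
        assert encode_onehot1(seq).sum() == len(seq)
        assert encode_onehot2(seq).sum() == len(seq) - 1
        assert set(np.unique(encode_onehot2(seq))) <= {0.0, 1.0}

    def test_injectivity_exhaustive_length4(self):
        # brute-force oracle: all 5^4 windows encode to distinct vectors
        seen1, seen2 = set(), set()
        for chars in itertools.product("ACGTN", repeat=4):
            seq = "".join(chars)
            seen1.add(encode_onehot1(seq).tobytes())
            seen2.add(encode_onehot2(seq).tobytes())
        assert len(seen1) == 5 ** 4
        assert len(seen2) == 5 ** 4


class TestAccumulatedFrequencies:
    def test_amnf_worked_example(self):
        v = encode_amnf("ACGTNA")
        assert np.allclose(v, [1, 1 / 2, 1 / 3, 1 / 4, 1 / 5, 2 / 6])
        assert np.round(v, 2).tolist() == [1, 0.5, 0.33, 0.25, 0.2, 0.33]

    def test_adnf_worked_example(self):
        v = encode_adnf("ACGTNA")
        assert np.round(v, 2).tolist() == [1, 0.5, 0.33, 0.25, 0.2]

    @pytest.mark.parametrize("fn,seq,expected", [
        (encode_amnf, "AAAA", [1, 1, 1, 1]),
        (encode_amnf, "AT", [1, 0.5]),
        (encode_adnf, "AAA", [1, 1]),
        (encode_adnf, "ACAC", [1, 0.5, 2 / 3]),
    ])
    def test_small_cases(self, fn, seq, expected):
        assert np.allclose(fn(seq), expected)

    @given(windows_st, st.integers(min_value=1, max_value=40))
    @settings(max_examples=150, derandomize=True)
    def test_prefix_consistency(self, seq, t):
        t = min(t, len(seq))
        full = encode_amnf(seq)
        assert np.array_equal(encode_amnf(seq[:t]), full[:t])
        if t >= 2:
            assert np.array_equal(encode_adnf(seq[:t]), encode_adnf(seq)[:t - 1])

    @given(windows_st)
    @settings(max_examples=100, derandomize=True)
    def test_value_range(self, seq):
        for v in (encode_amnf(seq), encode_adnf(seq)):
            assert np.all(v > 0) and np.all(v <= 1)
            assert v[0] == 1.0


def toy_table(values_by_token, n_props=1, kmer_size=2):
    tokens = kmer_tokens(kmer_size)
    values = np.zeros((len(tokens), n_props))
    for tok, val in values_by_token.items():
        values[tokens.index(tok)] = val
    return PropertyTable(kmer_size, tokens, tuple(f"p{i}" for i in range(n_props)),
                         values)


class TestPhysicochemical:
    def test_zero_table_gives_zero_vector(self, rng):
        table = toy_table({}, n_props=3)
        assert not encode_pcp(random_window(rng, 10), table).any()

    def test_count_times_property_by_hand(self):
        # "AAA" has two AA dinucleotides: entry = 2 * 2.0 = 4
        table = toy_table({t: 1.0 for t in kmer_tokens(2)} | {"AA": 2.0})
        v = encode_pcp("AAA", table)
        assert v[kmer_tokens(2).index("AA")] == 4.0
        assert np.count_nonzero(v) == 1

    def test_trinucleotide_by_hand(self):
        table = toy_table({"ACG": 0.5, "CGT": -1.0}, kmer_size=3)
        v = encode_pcp("ACGT", table)
        toks = kmer_tokens(3)
        assert v[toks.index("ACG")] == 0.5
        assert v[toks.index("CGT")] == -1.0
        assert np.count_nonzero(v) == 2

    def test_linearity_in_table(self, rng):
        table = default_dinucleotide_table()
        seq = random_window(rng, 41)
        assert np.allclose(encode_pcp(seq, table.scaled(3.0)),
                           3.0 * encode_pcp(seq, table))

    def test_default_dimensions(self, rng):
        seq = random_window(rng, 41)
        assert encode_pcp(seq, default_dinucleotide_table()).shape == (25 * 15,)
        assert encode_pcp(seq, default_trinucleotide_table()).shape == (125 * 11,)

    def test_normalize_flag_divides_by_kmer_count(self, rng):
        table = default_dinucleotide_table()
        seq = random_window(rng, 21)
        raw = encode_pcp(seq, table)
        assert np.allclose(encode_pcp(seq, table, normalize=True), raw / 20)

    def test_tsv_round_trip(self, tmp_path):
        table = default_dinucleotide_table()
        path = tmp_path / "props.tsv"
        write_property_table(table, path)
        back = read_property_table(path, kmer_size=2)
        assert back.properties == table.properties
        assert np.allclose(back.values, table.values)

    def test_incomplete_tsv_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("token\tp1\nAA\t1.0\n")  # 15 standard tokens missing
        with pytest.raises(ValueError, match="missing"):
            read_property_table(path, kmer_size=2)


class TestFusionAndMatrix:
    def test_fused_dimensions_on_41nt(self, rng):
        enc = get_encoder("FUSED", components=("ONEHOT1", "ONEHOT2"))
        assert enc(random_window(rng, 41)).shape == (205 + 1000,)

    def test_fused_density_pair_worked_example(self):
        v = encode_fused("ACGTNA", [get_encoder("AMNF"), get_encoder("ADNF")])
        assert v.shape == (11,)
        assert np.allclose(v, np.concatenate([encode_amnf("ACGTNA"),
                                              encode_adnf("ACGTNA")]))

    def test_self_fusion_doubles(self):
        enc = get_encoder("ONEHOT1")
        v = encode_fused("ACGT", [enc, enc])
        assert np.array_equal(v[:20], v[20:])

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            encode_fused("ACGT", [get_encoder("ONEHOT1")])

    def test_matrix_shape_and_order(self, rng):
        seqs = [random_window(rng, 41) for _ in range(6)]
        data = make_dataset(seqs, [1, 0, 1, 0, 1, 0])
        X = encode_matrix(data, "ONEHOT2")
        assert X.shape == (6, 1000)
        perm = [3, 1, 5, 0, 4, 2]
        Xp = encode_matrix(data.subset(perm), "ONEHOT2")
        assert np.array_equal(Xp, X[perm])

    def test_identical_windows_identical_rows(self):
        data = make_dataset(["ACGTA" * 8 + "A"] * 3, [1, 1, 1])
        X = encode_matrix(data, "ONEHOT1")
        assert np.array_equal(X[0], X[1]) and np.array_equal(X[1], X[2])

    def test_heterogeneous_lengths_rejected(self):
        data = make_dataset(["ACGT", "ACGTA"], [0, 1])
        with pytest.raises(ValueError, match="lengths"):
            encode_matrix(data, "ONEHOT1")

    @given(windows_st)
    @settings(max_examples=50, derandomize=True)
    def test_encoders_are_pure(self, seq):
        for enc in ("ONEHOT1", "ONEHOT2", "AMNF", "ADNF"):
            f = get_encoder(enc)
            assert np.array_equal(f(seq), f(seq))
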