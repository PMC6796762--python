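import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dataset, random_window
from sixma.encoders import (
    DEFAULT_ENCODINGS,
    ENCODING_DIMS,
    KNN_N_VALUES,
    build_knn_reference,
    encode_dataset,
    encode_dbe,
    encode_dbe_lpf,
    encode_kmer,
    encode_knn,
    encode_knn_batch,
    encode_lpf,
    encode_mbe,
    encode_num,
    encode_records,
    encode_rfhc,
    feature_names,
    similarity_score,
)
from sixma.seqio import CENTER_INDEX, LabeledDataset, SequenceRecord, WindowValidationError

windows = st.builds(
    lambda left, right: left + "A" + right,
    st.text("ACGT", min_size=20, max_size=20),
    st.text("ACGT", min_size=20, max_size=20),
)

_PURE_ENCODERS = {
    "NUM": encode_num,
    "MBE": encode_mbe,
    "DBE": encode_dbe,
    "LPF": encode_lpf,
    "DBE_LPF": encode_dbe_lpf,
    "RFHC": encode_rfhc,
    "KMER": encode_kmer,
}


@settings(max_examples=50, derandomize=True)
@given(windows)
def test_dimension_contract_and_purity(window):
    for name, fn in _PURE_ENCODERS.items():
        row = fn(window)
        assert row.shape == (ENCODING_DIMS[name],)
        assert np.all(np.isfinite(row))
        assert np.array_equal(row, fn(window))  # pure


@pytest.mark.parametrize("name", list(_PURE_ENCODERS) + ["KNN"])
def test_feature_names_match_dims(name):
    assert len(feature_names(name)) == ENCODING_DIMS[name]


def test_encoders_reject_invalid_windows():
    for fn in _PURE_ENCODERS.values():
        with pytest.raises(WindowValidationError):
            fn("A" * 40)


class TestNum:
    def test_poly_a_uniform(self):
        assert np.allclose(encode_num("A" * 41), 0.25)

    def test_alphabetical_mapping(self):
        w = "T" + "C" * 19 + "A" + "G" * 20
        row = encode_num(w)
        assert row[0] == 1.0  # leading T
        assert np.all(row[1:20] == 0.50)  # C flank
        assert np.all(row[20:] == 0.75)  # G flank (centre omitted)

    def test_central_adenine_omitted(self):
        # two windows differing only in flank content around the centre
        w1 = "C" * 20 + "A" + "C" * 20
        row = encode_num(w1)
        assert len(row) == 40 and np.all(row == 0.50)


class TestMbe:
    def test_one_hot_blocks(self, rng):
        w = random_window(rng)
        row = encode_mbe(w).reshape(41, 4)
        assert np.all(row.sum(axis=1) == 1)
        order = "ACGT"
        for i, base in enumerate(w):
            assert row[i, order.index(base)] == 1

    def test_printed_examples(self):
        assert np.array_equal(encode_mbe("A" * 41)[:4], [1, 0, 0, 0])
        w = "T" + "A" * 19 + "A" + "A" * 20
        assert np.array_equal(encode_mbe(w)[:4], [0, 0, 0, 1])


class TestDbe:
    @pytest.mark.parametrize(
        "dinuc,code",
        [("AA", [0, 0, 0, 0]), ("AT", [0, 0, 0, 1]), ("AC", [0, 0, 1, 0]),
         ("AG", [0, 0, 1, 1]), ("TA", [0, 1, 0, 0]), ("GG", [1, 1, 1, 1])],
    )
    def test_printed_codes(self, dinuc, code):
        w = dinuc + "C" * 18 + "A" + "C" * 20
        assert np.array_equal(encode_dbe(w)[:4], code)

    def test_bijection_over_16_dinucleotides(self):
        codes = {}
        for a in "ATCG":
            for b in "ATCG":
                w = a + b + "C" * 18 + "A" + "C" * 20
                codes[a + b] = tuple(encode_dbe(w)[:4])
        assert len(set(codes.values())) == 16
        # every code is a 4-bit vector
        assert all(set(c) <= {0.0, 1.0} for c in codes.values())


class TestLpf:
    def test_poly_a_prefix_fractions(self):
        expected = [(j - 1) / j for j in range(2, 42)]
        assert np.allclose(encode_lpf("A" * 41), expected)

    def test_first_value_always_half(self, rng):
        for _ in range(10):
            assert encode_lpf(random_window(rng))[0] == 0.5

    def test_matches_bruteforce_oracle(self, rng):
        def oracle(seq):
            out = []
            for j in range(2, 42):  # 1-based end position
                dinuc = seq[j - 2 : j]
                count = sum(
                    1 for e in range(2, j + 1) if seq[e - 2 : e] == dinuc
                )
                out.append(count / j)
            return np.array(out)

        for _ in range(25):
            w = random_window(rng)
            assert np.allclose(encode_lpf(w), oracle(w), atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        row = encode_lpf(random_window(rng))
        assert np.all(row > 0) and np.all(row <= 1)


class TestDbeLpf:
    def test_concatenation(self, rng):
        w = random_window(rng)
        row = encode_dbe_lpf(w)
        assert row.shape == (200,)
        assert np.array_equal(row[:160], encode_dbe(w))
        assert np.array_equal(row[160:], encode_lpf(w))
        assert set(np.unique(row[:160])) <= {0.0, 1.0}


class TestRfhc:
    @pytest.mark.parametrize(
        "base,abc",
        [("A", (1, 1, 1)), ("C", (0, 0, 1)), ("G", (1, 0, 0)), ("T", (0, 1, 0))],
    )
    def test_chemical_coordinates(self, base, abc):
        w = base + "C" * 19 + "A" + "C" * 20
        assert tuple(encode_rfhc(w)[:3]) == abc

    def test_density_first_position_is_one(self, rng):
        for _ in range(10):
            assert encode_rfhc(random_window(rng))[3] == 1.0

    def test_density_hand_example(self):
        w = "AACA" + "A" * 16 + "A" + "C" * 20
        row = encode_rfhc(w).reshape(41, 4)
        assert row[3, 3] == 0.75  # 3 As within the first 4 bases

    def test_homopolymer_density_all_one(self):
        row = encode_rfhc("A" * 41).reshape(41, 4)
        assert np.all(row[:, 3] == 1.0)

    def test_density_in_unit_interval(self, rng):
        row = encode_rfhc(random_window(rng)).reshape(41, 4)
        assert np.all(row[:, 3] > 0) and np.all(row[:, 3] <= 1)


class TestKmer:
    def test_poly_a_blocks(self):
        row = encode_kmer("A" * 41)
        assert np.array_equal(row[:4], [1, 0, 0, 0])
        assert row[4] == 1.0  # AA
        assert row[4 + 16 + 64 + 256] == 1.0  # AAAAA

    def test_blocks_sum_to_one(self, rng):
        row = encode_kmer(random_window(rng))
        offsets = [0, 4, 20, 84, 340, 1364]
        for lo, hi in zip(offsets, offsets[1:]):
            assert abs(row[lo:hi].sum() - 1.0) < 1e-9


class TestSimilarity:
    def test_identical_and_disjoint(self):
        assert similarity_score("A" * 41, "A" * 41) == 82
        assert similarity_score("A" * 41, "C" * 41) == -41

    def test_symmetry_and_oracle(self, rng):
        for _ in range(50):
            p1, p2 = random_window(rng), random_window(rng)
            expected = sum(2 if a == b else -1 for a, b in zip(p1, p2))
            assert similarity_score(p1, p2) == expected
            assert similarity_score(p1, p2) == similarity_score(p2, p1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            similarity_score("ACGT", "ACG")


class TestKnn:
    def test_reference_requires_128_records(self, rng):
        small = random_dataset(rng, 50, 50)
        with pytest.raises(ValueError, match="128"):
            build_knn_reference(small)

    def test_reference_snapshot(self, labeled300):
        ref = build_knn_reference(labeled300)
        assert ref.n_ref == 300
        assert ref.n_values == KNN_N_VALUES
        with pytest.raises(ValueError):
            ref.codes[0, 0] = 3  # immutable snapshot

    def test_known_neighbours(self, labeled300, rng):
        # plant two exact positive copies of the query in the reference
        query = SequenceRecord("query", random_window(rng))
        twins = [SequenceRecord(f"twin{i}", query.seq, label=1) for i in range(2)]
        ref = build_knn_reference(
            LabeledDataset(labeled300.records + twins)
        )
        feats = encode_knn(query, ref)
        assert feats.shape == (7,)
        assert feats[0] == 1.0  # both nearest neighbours positive
        assert np.all((feats >= 0) & (feats <= 1))

    def test_all_negative_neighbourhood(self, rng):
        # negatives share the query's flanks; positives are maximally far
        neg = [
            SequenceRecord(f"n{i}", "C" * 20 + "A" + "C" * 20, label=0)
            for i in range(140)
        ]
        pos = [
            SequenceRecord(f"p{i}", "G" * 20 + "A" + "G" * 20, label=1)
            for i in range(140)
        ]
        ref = build_knn_reference(LabeledDataset(neg + pos))
        feats = encode_knn(SequenceRecord("q", "C" * 20 + "A" + "C" * 20), ref)
        assert np.all(feats == 0.0)

    def test_exclude_self_changes_leaked_value(self, labeled300):
        rec = labeled300.records[0]  # a positive training record
        ref = build_knn_reference(labeled300)
        with_self = encode_knn(rec, ref, exclude_self=False)
        without_self = encode_knn(rec, ref, exclude_self=True)
        # with the self-match allowed, the top-2 neighbourhood contains the
        # record's own label; the guard must remove it
        assert with_self[0] >= 0.5
        assert not np.array_equal(with_self, without_self)

    def test_batch_matches_single(self, labeled300):
        ref = build_knn_reference(labeled300)
        recs = labeled300.records[:10]
        batch = encode_knn_batch(recs, ref, exclude_self=True)
        for i, rec in enumerate(recs):
            assert np.array_equal(batch[i], encode_knn(rec, ref, exclude_self=True))


def test_encode_dataset_dispatch(labeled300):
    ref = build_knn_reference(labeled300)
    for enc in DEFAULT_ENCODINGS:
        mat = encode_dataset(labeled300, enc, ref=ref)
        assert mat.values.shape == (300, ENCODING_DIMS[enc])
    with pytest.raises(KeyError):
        encode_dataset(labeled300, "NOPE")
    with pytest.raises(ValueError, match="reference"):
        encode_dataset(labeled300, "KNN")


def test_feature_matrix_tsv_export(tmp_path, labeled300):
    mat = encode_dataset(labeled300, "NUM")
    path = tmp_path / "num.tsv"
    mat.to_tsv(path, ids=labeled300.ids())
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[0] == "id"
    assert len(lines) == 301
    assert len(lines[1].split("\t")) == 41
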