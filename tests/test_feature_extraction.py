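"""Triplet, sequence-structure and thermodynamic feature extraction."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirfuse as mf
from mirfuse.feature_extraction import (
    SEQSTRUCT_LABELS,
    TRIPLET_LABELS,
    TooShortError,
    read_feature_matrix,
    write_feature_matrix,
)
from mirfuse.structure_fold import InvalidInputError

from conftest import random_rna


def oracle_triplet_counts(residues: str, symbols: str) -> dict:
    """Naive per-window tally, independent of the vector implementation."""
    pattern = symbols.replace(")", "(")
    tally = Counter()
    for i in range(len(residues) - 2):
        tally[residues[i + 1] + pattern[i : i + 3]] += 1
    return tally


def oracle_seqstruct_counts(residues: str, flags) -> dict:
    tally = Counter()
    for i in range(len(residues) - 2):
        code = "".join(str(int(f)) for f in flags[i : i + 3])
        tally[residues[i : i + 3] + code] += 1
    return tally


class TestTriplet32:
    def test_worked_nine_mer(self):
        """Window-by-window tally of GGGAAACCC/(((...)))."""
        seq = mf.RnaSequence("x", "GGGAAACCC")
        vec = mf.triplet32(seq, mf.DotBracket("(((...)))"), normalize=True)
        # 7 windows; middle letters G,G,A,A,A,C,C with normalized patterns
        expected = {
            "G(((": 1, "G((.": 1, "A(..": 1, "A...": 1,
            "A..(": 1, "C.((": 1, "C(((": 1,
        }
        for label, count in expected.items():
            assert vec[TRIPLET_LABELS.index(label)] == pytest.approx(count / 7)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_window_count_identity_and_normalization(self):
        rng = np.random.default_rng(0)
        seq = mf.RnaSequence("x", random_rna(rng, 70))
        structure = mf.fold(seq).structure
        raw = mf.triplet32(seq, structure, normalize=False)
        assert raw.sum() == 68  # L - 2 windows
        norm = mf.triplet32(seq, structure, normalize=True)
        assert norm.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((0 <= norm) & (norm <= 1)).all()

    def test_too_short_and_mismatch_errors(self):
        with pytest.raises(TooShortError):
            mf.triplet32(mf.RnaSequence("x", "AU"), mf.DotBracket(".."))
        with pytest.raises(InvalidInputError):
            mf.triplet32(mf.RnaSequence("x", "AUGC"), mf.DotBracket("..."))

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            res = random_rna(rng, int(rng.integers(10, 121)))
            seq = mf.RnaSequence("x", res)
            structure = mf.fold(seq).structure
            raw = mf.triplet32(seq, structure, normalize=False)
            oracle = oracle_triplet_counts(res, structure.symbols)
            for j, label in enumerate(TRIPLET_LABELS):
                assert raw[j] == oracle.get(label, 0)


class TestSeqStruct512:
    def test_label_example(self):
        seq = mf.RnaSequence("x", "AUG")
        vec = mf.seqstruct512(seq, [0, 0, 1], normalize=False)
        assert vec[SEQSTRUCT_LABELS.index("AUG001")] == 1
        assert vec.sum() == 1

    def test_labels_are_512_distinct(self):
        assert len(SEQSTRUCT_LABELS) == 512
        assert len(set(SEQSTRUCT_LABELS)) == 512

    def test_repeated_window(self):
        vec = mf.seqstruct512(
            mf.RnaSequence("x", "AAAA"), [0, 0, 0, 0], normalize=False
        )
        assert vec[SEQSTRUCT_LABELS.index("AAA000")] == 2
        assert vec.sum() == 2

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            res = random_rna(rng, int(rng.integers(10, 121)))
            seq = mf.RnaSequence("x", res)
            flags = mf.paired_flags(mf.fold(seq).structure)
            raw = mf.seqstruct512(seq, flags, normalize=False)
            assert raw.sum() == len(res) - 2
            oracle = oracle_seqstruct_counts(res, flags)
            for j, label in enumerate(SEQSTRUCT_LABELS):
                assert raw[j] == oracle.get(label, 0)


class TestDinucleotideShuffle:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_preserves_dinucleotides_and_ends(self, seed):
        rng = np.random.default_rng(seed)
        res = random_rna(rng, int(rng.integers(2, 80)))
        seq = mf.RnaSequence("x", res)
        shuffled = mf.dinucleotide_shuffle(seq, rng)
        assert len(shuffled.residues) == len(res)
        assert shuffled.residues[0] == res[0]
        assert shuffled.residues[-1] == res[-1]
        assert Counter(zip(shuffled.residues, shuffled.residues[1:])) == Counter(
            zip(res, res[1:])
        )

    def test_homopolymer_unique_arrangement(self):
        seq = mf.RnaSequence("x", "AAAA")
        out = mf.dinucleotide_shuffle(seq, np.random.default_rng(0))
        assert out.residues == "AAAA"

    def test_gcgc_counts_preserved(self):
        seq = mf.RnaSequence("x", "GCGCGC")
        out = mf.dinucleotide_shuffle(seq, np.random.default_rng(1))
        assert Counter(zip(out.residues, out.residues[1:])) == {
            ("G", "C"): 3,
            ("C", "G"): 2,
        }

    def test_same_seed_same_output(self):
        seq = mf.RnaSequence("x", "GGAUCCGGAUAUCGGGAUUACG")
        a = mf.dinucleotide_shuffle(seq, np.random.default_rng(42))
        b = mf.dinucleotide_shuffle(seq, np.random.default_rng(42))
        assert a.residues == b.residues

    def test_too_short(self):
        with pytest.raises(TooShortError):
            mf.dinucleotide_shuffle(mf.RnaSequence("x", "A"), np.random.default_rng(0))

    def test_shuffles_actually_vary(self):
        seq = mf.RnaSequence("x", "GGAUCCGGAUAUCGGGAUUACGCA")
        rng = np.random.default_rng(3)
        outs = {mf.dinucleotide_shuffle(seq, rng).residues for _ in range(20)}
        assert len(outs) > 1


class TestMfePvalue:
    def test_homopolymer_pvalue_zero(self):
        thermo = mf.mfe_pvalue(
            mf.RnaSequence("x", "AAAAAAAAAA"), n_shuffles=20,
            rng=np.random.default_rng(0),
        )
        assert thermo.p_value == 0.0
        assert thermo.mfe == 0.0

    def test_pvalue_bounded(self):
        rng = np.random.default_rng(1)
        seq = mf.RnaSequence("x", random_rna(rng, 40))
        thermo = mf.mfe_pvalue(seq, n_shuffles=30, rng=rng)
        assert 0.0 <= thermo.p_value <= 1.0

    def test_designed_hairpin_low_pvalue(self):
        """A perfect 20-bp stem out-pairs nearly every shuffle."""
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(10):
            hp = mf.gen_hairpin(
                mf.HairpinSpec(stem_length=20, loop_length=4, mismatch_rate=0.0),
                np.random.default_rng(seed),
            )
            thermo = mf.mfe_pvalue(hp, n_shuffles=200, rng=rng)
            hits += thermo.p_value < 0.05
        assert hits >= 9  # >= 95% of seeds at desk scale (10 draws)

    def test_deterministic_given_seed(self):
        seq = mf.RnaSequence("x", "GGAUCCGGAUAUCGGGAUUACG")
        a = mf.mfe_pvalue(seq, n_shuffles=25, rng=np.random.default_rng(5))
        b = mf.mfe_pvalue(seq, n_shuffles=25, rng=np.random.default_rng(5))
        assert a == b

    def test_pvalue_monotone_in_pair_count(self):
        """More original pairs => p-value cannot increase, shuffles fixed."""
        from mirfuse.structure_fold import max_pair_count

        rng = np.random.default_rng(9)
        seq = mf.RnaSequence("x", random_rna(rng, 40))
        shuffle_counts = [
            max_pair_count(mf.dinucleotide_shuffle(seq, rng)) for _ in range(50)
        ]
        pvals = [
            np.mean([c > orig for c in shuffle_counts])
            for orig in range(0, 15)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))


class TestBundleAndIO:
    def test_bundle_consistent_with_single_calls(self):
        seq = mf.RnaSequence("x", "GGGAAACCC")
        fr = mf.fold(seq)
        bundle = mf.build_feature_bundle(fr, n_shuffles=10, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            bundle.triplet32, mf.triplet32(seq, fr.structure, normalize=True)
        )
        np.testing.assert_allclose(
            bundle.seqstruct512,
            mf.seqstruct512(seq, mf.paired_flags(fr.structure), normalize=True),
        )
        np.testing.assert_allclose(bundle.hybrid34[:32], bundle.triplet32)
        assert bundle.hybrid34[32] == bundle.thermo.mfe
        assert bundle.hybrid34[33] == bundle.thermo.p_value

    def test_bundle_too_short(self):
        fr = mf.fold(mf.RnaSequence("x", "AU"))
        with pytest.raises(TooShortError):
            mf.build_feature_bundle(fr, n_shuffles=5, rng=np.random.default_rng(0))

    def test_feature_matrix_roundtrip_tolerates_reordered_columns(self, tmp_path):
        rng = np.random.default_rng(3)
        mat = rng.random((4, 32))
        path = tmp_path / "m.tsv"
        shuffled_labels = list(TRIPLET_LABELS)
        rng.shuffle(shuffled_labels)
        write_feature_matrix(path, mat[:, [TRIPLET_LABELS.index(l) for l in shuffled_labels]],
                             shuffled_labels, [f"s{i}" for i in range(4)])
        loaded, ids = read_feature_matrix(path, TRIPLET_LABELS)
        np.testing.assert_allclose(loaded, mat)
        assert ids == [f"s{i}" for i in range(4)]
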