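"""Pentamer shape lookup, A-tract rigidity, poly(dA/dT) coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucposlab import dna_features as df
from nucposlab.io_formats import Anchor, GenomeSequence, revcomp


def brute_force_rigidity(seq):
    """Enumerate all substrings; test each for the A^n T^m pattern."""
    L = len(seq)
    score = [0] * L

    def is_antm(s):
        if len(s) < 2:
            return False
        i = 0
        while i < len(s) and s[i] == "A":
            i += 1
        while i < len(s) and s[i] == "T":
            i += 1
        return i == len(s)

    for start in range(L):
        for end in range(start + 2, L + 1):
            sub = seq[start:end]
            if is_antm(sub):
                for i in range(start, end):
                    score[i] = max(score[i], end - start)
            elif not set(sub) <= {"A", "T"}:
                break  # no longer substring from this start can match
    return score


dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


@pytest.fixture
def toy_table():
    return df.PentamerShapeTable({"twist": {"AAAAA": -10.0}})


class TestShapeProfile:
    def test_lookup_positions(self, toy_table):
        # default 0 for unknown pentamers is not provided: undefined -> NaN;
        # use a table covering every pentamer of the sequence instead
        seq = "GGAAAAAGG"
        pentamers = {seq[i - 2 : i + 3] for i in range(2, len(seq) - 2)}
        table = df.PentamerShapeTable(
            {"twist": {p: (-10.0 if p == "AAAAA" else 0.0) for p in pentamers}}
        )
        prof = df.shape_profile(seq, table, "twist", smooth_window=1)
        np.testing.assert_array_equal(prof.values[2:7], [0, 0, -10, 0, 0])
        assert np.isnan(prof.values[:2]).all() and np.isnan(prof.values[7:]).all()

    def test_rollmean(self):
        seq = "GGAAAAAGG"
        pentamers = {seq[i - 2 : i + 3] for i in range(2, len(seq) - 2)}
        table = df.PentamerShapeTable(
            {"twist": {p: (-10.0 if p == "AAAAA" else 0.0) for p in pentamers}}
        )
        prof = df.shape_profile(seq, table, "twist", smooth_window=5)
        assert prof.values[4] == pytest.approx(-2.0)
        # window touches undefined flanks elsewhere
        assert np.isnan(prof.values[3])

    def test_no_pentamer_fits_all_undefined(self, toy_table):
        prof = df.shape_profile("ACGTA", toy_table, "twist", smooth_window=1)
        # only pentamer ACGTA is absent from the table -> everything NaN
        assert np.isnan(prof.values).all()

    def test_unknown_feature_rejected(self, toy_table):
        with pytest.raises(ValueError):
            df.shape_profile("ACGTACGTA", toy_table, "nope")

    def test_revcomp_closed_table_symmetry(self, rng, random_seq_factory):
        seq = random_seq_factory(60)
        import itertools

        table = {}
        for p in map("".join, itertools.product("ACGT", repeat=5)):
            if p not in table:
                v = float(rng.random())
                table[p] = v
                table[revcomp(p)] = v
        t = df.PentamerShapeTable({"f": table})
        fwd = df.shape_profile(seq, t, "f").values
        rev = df.shape_profile(revcomp(seq), t, "f").values
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)


class TestRigidity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAATTT", [6] * 6),
            ("TA", [0, 0]),
            ("GAAC", [0, 2, 2, 0]),
            ("AATAA", [3, 3, 3, 2, 2]),
            ("", []),
        ],
    )
    def test_examples(self, seq, expected):
        np.testing.assert_array_equal(df.rigidity_profile(seq).values, expected)

    @given(dna)
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, seq):
        np.testing.assert_array_equal(
            df.rigidity_profile(seq).values, brute_force_rigidity(seq)
        )

    @given(dna)
    @settings(max_examples=60, deadline=None)
    def test_revcomp_symmetry(self, seq):
        fwd = df.rigidity_profile(seq).values
        rev = df.rigidity_profile(revcomp(seq)).values
        np.testing.assert_array_equal(fwd, rev[::-1])

    @given(dna)
    @settings(max_examples=60, deadline=None)
    def test_gc_padding_leaves_scores_unchanged(self, seq):
        base = df.rigidity_profile(seq).values
        padded = df.rigidity_profile("G" + seq + "C").values
        np.testing.assert_array_equal(padded[1:-1], base)

    def test_n_never_matches(self):
        np.testing.assert_array_equal(
            df.rigidity_profile("ANATT").values, [0, 0, 3, 3, 3]
        )


class TestPolyAT:
    def test_overlapping_counts(self):
        cov = df.polyAT_coverage("AAAAAAA", k=6, mode="count")
        np.testing.assert_array_equal(cov["polyA"].values, [1, 2, 2, 2, 2, 2, 1])
        assert not cov["polyT"].values.any()

    def test_binary_mode(self):
        cov = df.polyAT_coverage("AAAAAAA", k=6, mode="binary")
        np.testing.assert_array_equal(cov["polyA"].values, np.ones(7))

    def test_no_matches(self):
        cov = df.polyAT_coverage("ACACAC", k=6)
        assert not cov["polyA"].values.any() and not cov["polyT"].values.any()

    @given(st.integers(6, 30))
    @settings(max_examples=20, deadline=None)
    def test_run_coverage_sum(self, r):
        """A maximal run of r >= k bases carries total count k*(r-k+1)."""
        k = 6
        cov = df.polyAT_coverage("G" + "A" * r + "G", k=k, mode="count")
        assert cov["polyA"].values.sum() == k * (r - k + 1)


class TestWindowFeatures:
    def test_identical_windows_mean_equals_single(self):
        g = GenomeSequence({"t1": "GG" + "AAATTT" + "GG" + "AAATTT" + "GG"})
        anchors = [Anchor("t1", 4, "+", "a"), Anchor("t1", 12, "+", "b")]
        mat, mean, dropped = df.window_features(g, anchors, 2, "rigidity")
        assert dropped == 0
        np.testing.assert_array_equal(mat[0], mat[1])
        np.testing.assert_array_equal(mean, mat[0])

    def test_minus_strand_orientation(self):
        seq = "GGGAATTTTGGGG"
        g = GenomeSequence({"t1": seq})
        plus = df.window_features(g, [Anchor("t1", 6, "+", "a")], 4, "rigidity")[0][0]
        # mirrored anchor on the reverse-complemented genome
        gm = GenomeSequence({"t1": revcomp(seq)})
        pos_m = len(seq) - 1 - 6
        minus = df.window_features(gm, [Anchor("t1", pos_m, "-", "a")], 4, "rigidity")[0][0]
        np.testing.assert_array_equal(plus, minus)

    def test_out_of_range_dropped(self):
        g = GenomeSequence({"t1": "ACGTACGTAC"})
        mat, _, dropped = df.window_features(
            g, [Anchor("t1", 1, "+", "a"), Anchor("t1", 5, "+", "b")], 3, "rigidity"
        )
        assert dropped == 1 and mat.shape == (1, 7)

    def test_no_survivors_is_error(self):
        g = GenomeSequence({"t1": "ACGT"})
        with pytest.raises(ValueError):
            df.window_features(g, [Anchor("t1", 0, "+", "a")], 10, "rigidity")
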