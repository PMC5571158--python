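"""Data-set filters and the three synthetic construction procedures."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from premirscan import datasets as ds
from premirscan.datasets import HairpinRecord
from premirscan import structure as st


def _rec(i, seq, **kw):
    return HairpinRecord(id=f"r{i}", seq=seq, **kw)


class TestFilters:
    def test_dedup_keeps_first_occurrence(self):
        recs = [_rec(0, "GGGAAACCC"), _rec(1, "GGGAAACCC"), _rec(2, "AAAAUUUU")]
        out = ds.dedup_identical(recs)
        assert [r.id for r in out] == ["r0", "r2"]

    def test_dedup_unique_and_empty(self):
        recs = [_rec(0, "GGGAAACCC"), _rec(1, "AAAAUUUU")]
        assert ds.dedup_identical(recs) == recs
        assert ds.dedup_identical([]) == []

    @pytest.mark.parametrize(
        "length,kept", [(35, False), (36, True), (180, True), (181, False)]
    )
    def test_length_bounds_inclusive(self, length, kept):
        recs = [_rec(0, "A" * length)]
        assert bool(ds.filter_by_length(recs)) is kept

    def test_length_invalid_bounds(self):
        with pytest.raises(ValueError):
            ds.filter_by_length([], min_len=10, max_len=5)

    @pytest.mark.parametrize("rpm,kept", [(100.0, True), (99.9, False)])
    def test_rpm_threshold(self, rpm, kept):
        recs = [_rec(0, "A" * 40, rpm=rpm)]
        assert bool(ds.filter_by_rpm(recs)) is kept

    def test_rpm_missing_metadata_lists_ids(self):
        recs = [_rec(0, "A" * 40, rpm=5.0), _rec(1, "C" * 40)]
        with pytest.raises(ValueError, match="r1"):
            ds.filter_by_rpm(recs)
        assert ds.filter_by_rpm([]) == []


class TestShuffled:
    def test_residue_multiset_preserved(self, small_hairpin_sets):
        pos, _ = small_hairpin_sets
        out = ds.make_shuffled(pos.records, seed=5)
        assert len(out) == len(pos.records)
        for orig, shuf in zip(pos.records, out.records):
            assert Counter(orig.seq) == Counter(shuf.seq)
            assert shuf.label == "negative"

    def test_homopolymer_fixed_point(self):
        out = ds.make_shuffled([_rec(0, "AAAA")], seed=1)
        assert out.records[0].seq == "AAAA"

    def test_seed_determinism(self, small_hairpin_sets):
        pos, _ = small_hairpin_sets
        a = ds.make_shuffled(pos.records, seed=5)
        b = ds.make_shuffled(pos.records, seed=5)
        c = ds.make_shuffled(pos.records, seed=6)
        assert [r.seq for r in a] == [r.seq for r in b]
        assert [r.seq for r in a] != [r.seq for r in c]

    def test_dinucleotide_preserving_option(self):
        seq = "GCAUGCAUGGCCAAUUGGCAUCGA"

        def dinucs(s):
            return Counter(s[i:i + 2] for i in range(len(s) - 1))

        out = ds.make_shuffled([_rec(0, seq)], seed=3,
                               preserve_dinucleotides=True)
        assert dinucs(out.records[0].seq) == dinucs(seq)

    def test_provenance_recorded(self, small_hairpin_sets):
        pos, _ = small_hairpin_sets
        out = ds.make_shuffled(pos.records, seed=5)
        assert out.provenance[0]["seed"] == 5


class TestNotBestFold:
    def test_structures_differ_sequences_unchanged(self, small_hairpin_sets):
        pos, _ = small_hairpin_sets
        out = ds.make_notbestfold(pos.records[:8])
        assert 0 < len(out) <= 8
        for r in out.records:
            orig_id = r.id.removesuffix("_nbf")
            orig = next(p for p in pos.records if p.id == orig_id)
            assert r.seq == orig.seq
            assert r.struct != st.fold(r.seq).structure
            st.parse_dotbracket(r.struct)

    def test_unfoldable_records_skipped_and_logged(self):
        out = ds.make_notbestfold([_rec(0, "A" * 40)])
        assert len(out) == 0
        assert out.provenance[0]["skipped"] == ["r0"]

    def test_small_stem_next_best(self):
        out = ds.make_notbestfold([_rec(0, "GGGAAACCC")])
        assert out.records[0].struct.count("(") == 2


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(11)
    return pd.DataFrame(
        rng.normal(size=(200, 6)), columns=[f"f{i}" for i in range(6)]
    )


class TestFeatureSpaceSets:
    @pytest.mark.parametrize("mode,lo_q,hi_q",
                             [("FR", 0.0, 1.0), ("BQ", 0.25, 0.75),
                              ("AM", 0.40, 0.60)])
    def test_containment(self, matrix, mode, lo_q, hi_q):
        out = ds.make_feature_space_set(matrix, mode, n=500, seed=2)
        assert out.shape == (500, 6)
        for c in matrix.columns:
            lo, hi = ds.quantile(matrix[c], lo_q), ds.quantile(matrix[c], hi_q)
            assert out[c].between(lo, hi).all()

    def test_interval_nesting(self, matrix):
        for c in matrix.columns:
            fr = (ds.quantile(matrix[c], 0), ds.quantile(matrix[c], 1))
            bq = (ds.quantile(matrix[c], .25), ds.quantile(matrix[c], .75))
            am = (ds.quantile(matrix[c], .40), ds.quantile(matrix[c], .60))
            assert fr[0] <= bq[0] <= am[0] <= am[1] <= bq[1] <= fr[1]

    def test_constant_column_stays_constant(self):
        m = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [0.0, 1.0, 2.0]})
        out = ds.make_feature_space_set(m, "FR", n=50, seed=0)
        assert (out["a"] == 2.0).all()

    def test_default_n_is_5000(self, matrix):
        out = ds.make_feature_space_set(matrix, "BQ", seed=0)
        assert len(out) == 5000

    def test_seed_determinism(self, matrix):
        a = ds.make_feature_space_set(matrix, "AM", n=100, seed=9)
        b = ds.make_feature_space_set(matrix, "AM", n=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ds.make_feature_space_set(pd.DataFrame(), "FR")


def test_quantile_linear_interpolation():
    assert ds.quantile([0.8, 0.9, 1.0, 1.0], 0.25) == pytest.approx(0.875)
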