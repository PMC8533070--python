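"""Gap-aware projection and the per-column conservation profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amycon.model import (
    AlignmentMatrix,
    AnalysisConfig,
    ConsistencyError,
    Region,
    RegionLabel,
)
from amycon.projection import (
    build_profile,
    column_amyloid_fraction,
    column_identity,
    column_to_seq_map,
    seq_to_column_map,
)

from helpers import (
    oracle_column_amyloid_fraction,
    random_alignment,
    random_regions,
)


def _amyl(seq_id, start, end):
    return Region(seq_id, start, end, RegionLabel.AMYLOIDOGENIC)


class TestCoordinateMaps:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ("A-CD", {1: 1, 2: 3, 3: 4}),
            ("ACD", {1: 1, 2: 2, 3: 3}),
            ("--A", {1: 3}),
        ],
    )
    def test_seq_to_column_examples(self, row, expected):
        assert seq_to_column_map(row) == expected

    @given(st.text(alphabet="AC-", min_size=1, max_size=60))
    def test_round_trip_identity_on_non_gap_positions(self, row):
        forward = seq_to_column_map(row)
        inverse = column_to_seq_map(row)
        for residue, column in forward.items():
            assert inverse[column] == residue
        assert len(forward) == len(row) - row.count("-")


class TestColumnAmyloidFraction:
    def test_fraction_over_all_rows(self):
        matrix = AlignmentMatrix(rows=[("a", "QQ"), ("b", "QQ"), ("c", "QQ")])
        frac = column_amyloid_fraction(
            matrix, {"a": [_amyl("a", 1, 1)], "b": [_amyl("b", 1, 1)]}
        )
        np.testing.assert_allclose(frac, [2 / 3, 0.0])

    def test_denominator_excludes_gap_rows(self):
        matrix = AlignmentMatrix(rows=[("a", "Q"), ("b", "Q"), ("c", "-")])
        frac = column_amyloid_fraction(
            matrix, {"a": [_amyl("a", 1, 1)], "b": [_amyl("b", 1, 1)]}
        )
        np.testing.assert_allclose(frac, [1.0])

    def test_no_regions_all_zero(self):
        matrix = AlignmentMatrix(rows=[("a", "QN-"), ("b", "QNV")])
        assert (column_amyloid_fraction(matrix, {}) == 0).all()

    def test_unknown_sequence_rejected(self):
        matrix = AlignmentMatrix(rows=[("a", "QN")])
        with pytest.raises(ConsistencyError, match="ghost"):
            column_amyloid_fraction(matrix, {"ghost": [_amyl("ghost", 1, 1)]})


class TestColumnIdentity:
    def test_unanimous_column(self):
        matrix = AlignmentMatrix(rows=[("a", "A"), ("b", "A"), ("c", "A")])
        np.testing.assert_allclose(column_identity(matrix), [1.0])

    def test_modal_frequency_over_non_gaps(self):
        matrix = AlignmentMatrix(
            rows=[("a", "A"), ("b", "A"), ("c", "G"), ("d", "-")]
        )
        np.testing.assert_allclose(column_identity(matrix), [2 / 3])

    def test_all_gap_column_scores_zero(self):
        matrix = AlignmentMatrix(rows=[("a", "-Q"), ("b", "-Q")])
        np.testing.assert_allclose(column_identity(matrix), [0.0, 1.0])


class TestBuildProfile:
    def test_single_sequence_profile_is_region_indicator(self):
        matrix = AlignmentMatrix(rows=[("a", "QQQQQ")])
        profile = build_profile(matrix, {"a": [_amyl("a", 2, 3)]})
        np.testing.assert_allclose(profile.amyloid_fraction, [0, 1, 1, 0, 0])
        assert not profile.masked.any()

    def test_gap_heavy_columns_masked(self):
        matrix = AlignmentMatrix(
            rows=[("a", "Q-"), ("b", "Q-"), ("c", "QQ"), ("d", "-Q")]
        )
        profile = build_profile(matrix, {},
                                AnalysisConfig(gap_mask_fraction=0.4))
        assert profile.masked.tolist() == [False, True]

    def test_row_permutation_invariance(self, rng):
        matrix = random_alignment(rng, 8, 60)
        regions = {
            rid: random_regions(rng, rid, len(row) - row.count("-"))
            for rid, row in matrix.rows
        }
        profile = build_profile(matrix, regions)
        perm = list(range(8))
        rng.shuffle(perm)
        shuffled = AlignmentMatrix(rows=[matrix.rows[i] for i in perm])
        profile2 = build_profile(shuffled, regions)
        np.testing.assert_allclose(profile.amyloid_fraction,
                                   profile2.amyloid_fraction)
        np.testing.assert_allclose(profile.identity, profile2.identity)

    def test_full_length_masks_give_unit_fractions(self, rng):
        matrix = random_alignment(rng, 6, 40)
        regions = {
            rid: [_amyl(rid, 1, len(row) - row.count("-"))]
            for rid, row in matrix.rows
        }
        frac = column_amyloid_fraction(matrix, regions)
        codes = np.array([list(row) for _, row in matrix.rows])
        non_all_gap = (codes != "-").any(axis=0)
        assert (frac[non_all_gap] == 1.0).all()

    def test_region_past_sequence_end_rejected(self):
        matrix = AlignmentMatrix(rows=[("a", "QN")])
        with pytest.raises(ConsistencyError, match="exceeds"):
            column_amyloid_fraction(matrix, {"a": [_amyl("a", 1, 5)]})


class TestOracleEquivalence:
    @given(st.integers(0, 2**31 - 1))
    def test_matches_rasterize_and_count(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_alignment(
            rng, int(rng.integers(1, 20)), int(rng.integers(1, 200))
        )
        regions = {
            rid: random_regions(rng, rid, len(row) - row.count("-"))
            for rid, row in matrix.rows
        }
        frac = column_amyloid_fraction(matrix, regions)
        np.testing.assert_allclose(
            frac, oracle_column_amyloid_fraction(matrix, regions)
        )


class TestProfileTsvRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        matrix = random_alignment(rng, 5, 30)
        profile = build_profile(matrix, {})
        path = tmp_path / "profile.tsv"
        profile.write_tsv(path)
        from amycon.projection import ColumnProfile

        back = ColumnProfile.from_tsv(path)
        np.testing.assert_allclose(back.gap_fraction, profile.gap_fraction,
                                   atol=1e-6)
        assert (back.masked == profile.masked).all()
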