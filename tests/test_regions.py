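"""Region calling against per-residue boolean oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amycon.model import (
    ConsistencyError,
    ProteinRecord,
    Region,
    RegionLabel,
    ScoreTrack,
    TrackKind,
)
from amycon.regions import (
    call_amyloidogenic_regions,
    call_arch_regions,
    call_disordered_segments,
    is_potential_amyloid,
    merge_regions,
)
from amycon.scoring import ArchCandidate

from helpers import (
    oracle_amyloidogenic,
    oracle_arch_track,
    oracle_disordered,
    regions_as_tuples,
)


def _dis(values, seq_id="s"):
    return ScoreTrack(seq_id, TrackKind.DISORDER, values)


def _arch(values, seq_id="s"):
    return ScoreTrack(seq_id, TrackKind.ARCH_CUMULATIVE, values)


def _region(start, end, label=RegionLabel.ARCH, seq_id="s", score=None):
    return Region(seq_id, start, end, label, score)


class TestDisorderedSegments:
    def test_runs_above_cutoff(self):
        regions = call_disordered_segments(_dis([0.1, 0.4, 0.5, 0.2, 0.35]), 0.3)
        assert regions_as_tuples(regions) == [(2, 3), (5, 5)]

    def test_all_below_cutoff_empty(self):
        assert call_disordered_segments(_dis([0.1, 0.3, 0.2]), 0.3) == []

    def test_cutoff_is_strict(self):
        # "more than 0.3": exactly 0.3 is NOT unstructured
        assert call_disordered_segments(_dis([0.3, 0.3]), 0.3) == []


class TestArchRegions:
    @staticmethod
    def _candidate(start, end, score, seq_id="s"):
        s1 = Region(seq_id, start, start + 3, RegionLabel.ARCH)
        loop = Region(seq_id, start + 4, end - 4, RegionLabel.ARCH)
        s2 = Region(seq_id, end - 3, end, RegionLabel.ARCH)
        return ArchCandidate(seq_id, s1, s2, loop, score, score)

    def test_candidate_spans_merge(self):
        a = self._candidate(5, 20, 0.6)
        b = self._candidate(15, 28, 0.8)
        regions = call_arch_regions([a, b], 0.575)
        assert regions_as_tuples(regions) == [(5, 28)]
        assert regions[0].score == 0.8

    def test_track_runs_at_threshold(self):
        regions = call_arch_regions(_arch([0.6, 0.6, 0.5]), 0.575)
        assert regions_as_tuples(regions) == [(1, 2)]

    def test_threshold_comparison_is_inclusive(self):
        # score exactly 0.575 qualifies under the default >= convention
        regions = call_arch_regions(_arch([0.575]), 0.575)
        assert regions_as_tuples(regions) == [(1, 1)]
        assert call_arch_regions(_arch([0.575]), 0.575, strict=True) == []

    def test_nothing_above_threshold(self):
        assert call_arch_regions(_arch([0.1, 0.5]), 0.575) == []


class TestAmyloidogenicRegions:
    def test_full_containment_retained_unmodified(self):
        arch = [_region(10, 30)]
        dis = [_region(5, 40, RegionLabel.DISORDERED)]
        out = call_amyloidogenic_regions(arch, dis, 0.5)
        assert regions_as_tuples(out) == [(10, 30)]
        assert out[0].label is RegionLabel.AMYLOIDOGENIC

    def test_minority_overlap_dropped(self):
        arch = [_region(10, 30)]  # 21 residues
        dis = [_region(25, 60, RegionLabel.DISORDERED)]  # overlap 6 -> 0.286
        assert call_amyloidogenic_regions(arch, dis, 0.5) == []

    def test_empty_disorder_gives_empty_result(self):
        assert call_amyloidogenic_regions([_region(1, 5)], [], 0.5) == []

    def test_cross_sequence_mixing_rejected(self):
        with pytest.raises(ConsistencyError):
            call_amyloidogenic_regions(
                [_region(1, 5, seq_id="a")],
                [_region(1, 5, RegionLabel.DISORDERED, seq_id="b")],
            )

    def test_overlap_fraction_limits(self):
        arch = [_region(10, 30)]
        dis = [_region(30, 30, RegionLabel.DISORDERED)]  # 1/21 overlap
        assert call_amyloidogenic_regions(arch, dis, 1e-9) != []  # any overlap
        assert call_amyloidogenic_regions(arch, dis, 1.0) == []  # containment
        contained = [_region(10, 30, RegionLabel.DISORDERED)]
        assert call_amyloidogenic_regions(arch, contained, 1.0) != []


class TestIsPotentialAmyloid:
    def test_definition(self):
        assert not is_potential_amyloid([])
        assert is_potential_amyloid([_region(1, 2, RegionLabel.AMYLOIDOGENIC)])
        five = [_region(i, i + 1, RegionLabel.AMYLOIDOGENIC) for i in
                (1, 10, 20, 30, 40)]
        assert is_potential_amyloid(five)


class TestOracleEquivalence:
    @given(st.integers(0, 2**31 - 1))
    def test_matches_boolean_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(1, 200))
        dis_values = rng.random(length)
        arch_values = rng.random(length)
        disordered = call_disordered_segments(_dis(dis_values), 0.3)
        arch = call_arch_regions(_arch(arch_values), 0.575)
        amyl = call_amyloidogenic_regions(arch, disordered, 0.5)
        assert regions_as_tuples(disordered) == oracle_disordered(dis_values, 0.3)
        assert regions_as_tuples(arch) == oracle_arch_track(arch_values, 0.575)
        assert regions_as_tuples(amyl) == oracle_amyloidogenic(
            regions_as_tuples(arch), regions_as_tuples(disordered), 0.5, length
        )

    @given(st.integers(0, 2**31 - 1))
    def test_outputs_sorted_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(int(rng.integers(1, 120)))
        for regions in (
            call_disordered_segments(_dis(values), 0.4),
            call_arch_regions(_arch(values), 0.6),
        ):
            for a, b in zip(regions, regions[1:]):
                assert a.end < b.start


class TestMonotonicity:
    @given(st.integers(0, 2**31 - 1))
    def test_raising_thresholds_never_enlarges_calls(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(int(rng.integers(1, 150)))
        lo, hi = sorted(rng.random(2))
        dis_lo = set()
        for r in call_disordered_segments(_dis(values), lo):
            dis_lo.update(range(r.start, r.end + 1))
        dis_hi = set()
        for r in call_disordered_segments(_dis(values), hi):
            dis_hi.update(range(r.start, r.end + 1))
        assert dis_hi <= dis_lo
        arch_lo = set()
        for r in call_arch_regions(_arch(values), lo):
            arch_lo.update(range(r.start, r.end + 1))
        arch_hi = set()
        for r in call_arch_regions(_arch(values), hi):
            arch_hi.update(range(r.start, r.end + 1))
        assert arch_hi <= arch_lo


class TestMergeRegions:
    def test_touching_regions_merge_and_keep_max_score(self):
        merged = merge_regions(
            [_region(1, 5, score=0.6), _region(6, 9, score=0.9)]
        )
        assert regions_as_tuples(merged) == [(1, 9)]
        assert merged[0].score == 0.9

    def test_disjoint_regions_untouched(self):
        merged = merge_regions([_region(1, 2), _region(5, 6)])
        assert regions_as_tuples(merged) == [(1, 2), (5, 6)]
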