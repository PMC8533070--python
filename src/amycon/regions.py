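"""Region calling: disordered segments, arch regions, and amyloid calls.

The amyloidogenicity rule is the published one: a protein (or part of it)
is amyloidogenic if at least one above-threshold beta-arch lies in an
unstructured region.  Comparison conventions, fixed here and documented in
docs/methods.md:

* disorder: a residue is unstructured iff its score is **strictly greater**
  than the cutoff (default 0.3), matching the published "more than 0.3";
* arch: a residue/candidate qualifies at score **>= threshold** (default
  0.575) — pass ``strict=True`` for a strict comparison;
* "located in an unstructured region" is quantified as residue-overlap
  fraction >= ``overlap_fraction`` (default 0.5, i.e. majority of the arch
  inside disorder; 1.0 is full containment, a tiny epsilon is any-overlap).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .model import ConsistencyError, Region, RegionLabel, ScoreTrack, TrackKind
from .scoring import ArchCandidate


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based inclusive (start, end) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.size:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def merge_regions(regions: Iterable[Region]) -> list[Region]:
    """Merge overlapping or touching same-label regions; keep the max score.

    Output is sorted by start and pairwise disjoint.
    """
    pool = sorted(regions, key=lambda r: (r.start, r.end))
    if not pool:
        return []
    merged: list[Region] = [pool[0]]
    for region in pool[1:]:
        last = merged[-1]
        if region.seq_id != last.seq_id:
            raise ConsistencyError(
                f"cannot merge regions from different sequences "
                f"({last.seq_id!r} vs {region.seq_id!r})"
            )
        if region.start <= last.end + 1:
            score = max(
                (s for s in (last.score, region.score) if s is not None),
                default=None,
            )
            merged[-1] = Region(
                seq_id=last.seq_id,
                start=last.start,
                end=max(last.end, region.end),
                label=last.label,
                score=score,
            )
        else:
            merged.append(region)
    return merged


def call_disordered_segments(
    track: ScoreTrack, cutoff: float = 0.3
) -> list[Region]:
    """Maximal runs of residues with disorder score strictly above cutoff."""
    if track.kind is not TrackKind.DISORDER:
        raise ConsistencyError(f"expected a disorder track, got {track.kind.value}")
    return [
        Region(track.seq_id, start, end, RegionLabel.DISORDERED)
        for start, end in _runs(track.values > cutoff)
    ]


def call_arch_regions(
    source: Union[ScoreTrack, Sequence[ArchCandidate]],
    threshold: float = 0.575,
    strict: bool = False,
) -> list[Region]:
    """Above-threshold arch regions from a cumulative track or candidates.

    From a track: maximal runs of score >= threshold.  From candidates:
    each qualifying candidate contributes its full strand1..strand2 span and
    overlapping spans are merged.  Each region carries the maximum
    contributing score.
    """
    if isinstance(source, ScoreTrack):
        if source.kind is not TrackKind.ARCH_CUMULATIVE:
            raise ConsistencyError(
                f"expected an arch_cumulative track, got {source.kind.value}"
            )
        qualifies = (
            source.values > threshold if strict else source.values >= threshold
        )
        out = []
        for start, end in _runs(qualifies):
            score = float(source.values[start - 1 : end].max())
            out.append(Region(source.seq_id, start, end, RegionLabel.ARCH, score))
        return out
    spans = [
        Region(c.seq_id, c.start, c.end, RegionLabel.ARCH, c.norm_score)
        for c in source
        if (c.norm_score > threshold if strict else c.norm_score >= threshold)
    ]
    return merge_regions(spans)


def call_amyloidogenic_regions(
    arch_regions: Sequence[Region],
    disordered: Sequence[Region],
    overlap_fraction: float = 0.5,
) -> list[Region]:
    """Arch regions whose overlap with disorder reaches ``overlap_fraction``.

    An arch region is retained iff the fraction of its residues lying inside
    any disordered segment is >= ``overlap_fraction``; retained regions keep
    their original bounds (no clipping to the disordered segment) and are
    merged if overlapping.
    """
    seq_ids = {r.seq_id for r in arch_regions} | {r.seq_id for r in disordered}
    if len(seq_ids) > 1:
        raise ConsistencyError(
            f"regions from multiple sequences mixed: {sorted(seq_ids)}"
        )
    disordered = merge_regions(list(disordered)) if disordered else []
    kept: list[Region] = []
    for arch in arch_regions:
        covered = sum(arch.overlap_length(d) for d in disordered)
        if covered / arch.length >= overlap_fraction:
            kept.append(
                Region(arch.seq_id, arch.start, arch.end,
                       RegionLabel.AMYLOIDOGENIC, arch.score)
            )
    return merge_regions(kept)


def is_potential_amyloid(amyloidogenic_regions: Sequence[Region]) -> bool:
    """A sequence is a potential amyloid iff it has >= 1 amyloidogenic region."""
    return len(amyloidogenic_regions) > 0


def summarize_amyloidogenicity(
    regions_by_seq: dict[str, Sequence[Region]]
) -> pd.DataFrame:
    """Per-protein summary: region count and the potential-amyloid verdict."""
    rows = [
        {
            "seq_id": seq_id,
            "n_amyloidogenic_regions": len(regions),
            "is_potential_amyloid": is_potential_amyloid(regions),
        }
        for seq_id, regions in regions_by_seq.items()
    ]
    return pd.DataFrame(rows, columns=[
        "seq_id", "n_amyloidogenic_regions", "is_potential_amyloid"
    ])
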