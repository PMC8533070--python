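"""Calling alignment regions with conserved amyloidogenic properties.

A conserved-amyloid region is a run of >= ``min_run`` consecutive unmasked
columns whose amyloid fraction reaches ``conservation_threshold``; masked
(gap-rich) columns break runs.  For each called region the amyloid-vs-
sequence-conservation contrast (mean amyloid fraction minus mean residue
identity over the region's unmasked columns) quantifies whether the
tendency to aggregate is conserved above and beyond plain sequence
similarity.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .model import AlignmentMatrix, ConsistencyError, Region, RegionLabel
from .projection import ColumnProfile, column_to_seq_map

ALIGNMENT_SEQ_ID = "alignment"


def call_conserved_amyloid_regions(
    profile: ColumnProfile,
    conservation_threshold: float = 0.7,
    min_run: int = 5,
) -> list[Region]:
    """Runs of qualifying unmasked columns, on alignment coordinates.

    Returned regions use ``seq_id="alignment"`` and carry the mean amyloid
    fraction of their columns as the score.
    """
    ok = (profile.amyloid_fraction >= conservation_threshold) & ~profile.masked
    padded = np.concatenate([[False], ok, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    out = []
    for start, end in zip(starts.tolist(), ends.tolist()):
        if end - start + 1 >= min_run:
            score = float(profile.amyloid_fraction[start - 1 : end].mean())
            out.append(
                Region(ALIGNMENT_SEQ_ID, start, end,
                       RegionLabel.CONSERVED_AMYLOID, score)
            )
    return out


def conservation_contrast(
    profile: ColumnProfile, regions: Sequence[Region]
) -> pd.DataFrame:
    """Per-region means of amyloid fraction and identity, and their difference.

    Means are taken over the region's unmasked columns; a region with no
    unmasked column is an error.
    """
    rows = []
    for i, region in enumerate(regions, start=1):
        cols = slice(region.start - 1, region.end)
        unmasked = ~profile.masked[cols]
        if not unmasked.any():
            raise ConsistencyError(
                f"region {region.start}..{region.end} has no unmasked columns"
            )
        amyl = float(profile.amyloid_fraction[cols][unmasked].mean())
        ident = float(profile.identity[cols][unmasked].mean())
        rows.append(
            {
                "region": i,
                "start_column": region.start,
                "end_column": region.end,
                "n_unmasked_columns": int(unmasked.sum()),
                "mean_amyloid_fraction": amyl,
                "mean_identity": ident,
                "difference": amyl - ident,
            }
        )
    return pd.DataFrame(rows, columns=[
        "region", "start_column", "end_column", "n_unmasked_columns",
        "mean_amyloid_fraction", "mean_identity", "difference",
    ])


def back_project_regions(
    alignment: AlignmentMatrix, regions: Sequence[Region]
) -> dict[str, list[Region]]:
    """Project alignment-coordinate regions back onto each member sequence.

    For each row, a region maps to the span from its first to its last
    non-gap residue within the column interval; rows that are all-gap over
    the interval contribute nothing.
    """
    out: dict[str, list[Region]] = {}
    for seq_id, row in alignment.rows:
        inverse = column_to_seq_map(row, alignment.gap_char)
        projected = []
        for region in regions:
            residues = [
                inverse[c]
                for c in range(region.start, region.end + 1)
                if c in inverse
            ]
            if residues:
                projected.append(
                    Region(seq_id, min(residues), max(residues),
                           RegionLabel.CONSERVED_AMYLOID, region.score)
                )
        if projected:
            out[seq_id] = projected
    return out
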