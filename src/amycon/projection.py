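"""Gap-aware projection of per-sequence calls onto alignment columns.

The central statistic is the per-column amyloid fraction: among the rows
that have a residue (not a gap) at a column, the fraction whose residue
falls inside an amyloidogenic region of that sequence.  The denominator is
the non-gap row count — membership of "the corresponding amino acid" in a
region presumes the amino acid exists in that sequence.  Columns dominated
by gaps are masked rather than interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignmentMatrix,
    AnalysisConfig,
    ConsistencyError,
    Region,
)


def seq_to_column_map(row: str, gap_char: str = "-") -> dict[int, int]:
    """Map 1-based residue index -> 1-based alignment column for one row."""
    return {
        res + 1: col + 1
        for res, col in enumerate(
            np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8)
                           != ord(gap_char)).tolist()
        )
    }


def column_to_seq_map(row: str, gap_char: str = "-") -> dict[int, int]:
    """Inverse of :func:`seq_to_column_map`, defined on non-gap columns only."""
    return {col: res for res, col in seq_to_column_map(row, gap_char).items()}


def _codes(matrix: AlignmentMatrix) -> np.ndarray:
    """(n_rows, n_columns) uint8 view of the alignment."""
    return np.array(
        [np.frombuffer(row.encode(), dtype=np.uint8) for _, row in matrix.rows]
    )


def _region_mask(length: int, regions: Sequence[Region]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for region in regions:
        if region.end > length:
            raise ConsistencyError(
                f"region {region.start}..{region.end} on {region.seq_id!r} "
                f"exceeds sequence length {length}"
            )
        mask[region.start - 1 : region.end] = True
    return mask


def column_gap_fraction(alignment: AlignmentMatrix) -> np.ndarray:
    codes = _codes(alignment)
    return (codes == ord(alignment.gap_char)).mean(axis=0)


def column_amyloid_fraction(
    alignment: AlignmentMatrix,
    regions_by_seq: Mapping[str, Sequence[Region]],
) -> np.ndarray:
    """Fraction of non-gap rows per column whose residue is amyloidogenic.

    ``regions_by_seq`` maps seq_id -> that sequence's amyloidogenic regions
    (sequence coordinates).  All-gap columns get fraction 0.
    """
    known = set(alignment.ids())
    for seq_id in regions_by_seq:
        if seq_id not in known:
            raise ConsistencyError(
                f"amyloid regions given for unknown alignment row {seq_id!r}"
            )
    n_cols = alignment.n_columns
    nongap = np.zeros(n_cols, dtype=int)
    amyloid = np.zeros(n_cols, dtype=int)
    gap = ord(alignment.gap_char)
    for seq_id, row in alignment.rows:
        row_codes = np.frombuffer(row.encode(), dtype=np.uint8)
        cols = np.flatnonzero(row_codes != gap)
        nongap[cols] += 1
        regions = regions_by_seq.get(seq_id, ())
        if regions:
            mask = _region_mask(cols.size, regions)
            amyloid[cols[mask]] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(nongap > 0, amyloid / np.maximum(nongap, 1), 0.0)
    return frac


def column_identity(alignment: AlignmentMatrix) -> np.ndarray:
    """Per-column modal-residue frequency among non-gap residues.

    The baseline "sequence conservation" measure: 1.0 for a unanimous
    column, lower for diverse columns; all-gap columns score 0.
    """
    codes = _codes(alignment)
    gap = ord(alignment.gap_char)
    n_cols = alignment.n_columns
    out = np.zeros(n_cols, dtype=float)
    for c in range(n_cols):
        col = codes[:, c]
        col = col[col != gap]
        if col.size:
            out[c] = np.bincount(col).max() / col.size
    return out


@dataclass
class ColumnProfile:
    """Per-alignment-column statistics over a family.

    Arrays are indexed by 0-based column; reports print 1-based column
    numbers.  ``masked`` marks columns whose gap fraction exceeds the
    configured mask threshold (plus all-gap columns unconditionally).
    """

    amyloid_fraction: np.ndarray
    gap_fraction: np.ndarray
    identity: np.ndarray
    masked: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        sizes = {
            self.amyloid_fraction.size,
            self.gap_fraction.size,
            self.identity.size,
            self.masked.size,
        }
        if len(sizes) != 1:
            raise ConsistencyError("profile arrays have inconsistent lengths")

    @property
    def n_columns(self) -> int:
        return int(self.amyloid_fraction.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "amyloid_fraction": self.amyloid_fraction,
                "gap_fraction": self.gap_fraction,
                "identity": self.identity,
                "masked": self.masked.astype(bool),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["amyloid_fraction"] = df["amyloid_fraction"].map(lambda v: f"{v:.6g}")
        df["gap_fraction"] = df["gap_fraction"].map(lambda v: f"{v:.6g}")
        df["identity"] = df["identity"].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_sequences: int = 0) -> "ColumnProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            amyloid_fraction=df["amyloid_fraction"].to_numpy(dtype=float),
            gap_fraction=df["gap_fraction"].to_numpy(dtype=float),
            identity=df["identity"].to_numpy(dtype=float),
            masked=df["masked"].to_numpy(dtype=bool),
            n_sequences=n_sequences,
        )


def build_profile(
    alignment: AlignmentMatrix,
    regions_by_seq: Mapping[str, Sequence[Region]],
    config: Optional[AnalysisConfig] = None,
) -> ColumnProfile:
    """Assemble the full per-column profile for an alignment."""
    config = config or AnalysisConfig()
    gap_fraction = column_gap_fraction(alignment)
    masked = (gap_fraction > config.gap_mask_fraction) | (gap_fraction >= 1.0)
    return ColumnProfile(
        amyloid_fraction=column_amyloid_fraction(alignment, regions_by_seq),
        gap_fraction=gap_fraction,
        identity=column_identity(alignment),
        masked=masked,
        n_sequences=alignment.n_rows,
    )
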