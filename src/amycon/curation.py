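"""Ortholog-set curation: the sequence filters applied before realignment.

Filter order is fixed: manual exclusions -> species-level deduplication ->
C-terminal fragment removal -> over-long outlier removal.  Each filter is
single-pass: the length median it uses is computed once over its own input,
before any drop.  Every dropped record carries a machine-readable reason
code and the metric that triggered it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AlignmentMatrix, AnalysisConfig, ConsistencyError, ProteinRecord

logger = logging.getLogger(__name__)

REASON_EXCLUDED = "manual_exclude"
REASON_DUPLICATE = "duplicate_species"
REASON_FRAGMENT = "cterminal_fragment"
REASON_OUTLIER = "length_outlier"


@dataclass(frozen=True)
class DroppedRecord:
    """A removed record, why it was removed, and the deciding metric."""

    record: ProteinRecord
    reason: str
    metric: str


@dataclass
class CurationResult:
    kept: list[ProteinRecord]
    dropped: list[DroppedRecord]


def apply_exclusions(
    records: Sequence[ProteinRecord], exclude_ids: Iterable[str]
) -> tuple[list[ProteinRecord], list[DroppedRecord]]:
    """Remove records whose id is on a manual exclusion list."""
    excluded = set(exclude_ids)
    kept, dropped = [], []
    for rec in records:
        if rec.id in excluded:
            dropped.append(DroppedRecord(rec, REASON_EXCLUDED, "listed"))
        else:
            kept.append(rec)
    return kept, dropped


def dedupe_by_species(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[DroppedRecord]]:
    """Keep one record per species: the longest, ties to the smallest id."""
    for rec in records:
        if not rec.species:
            raise ConsistencyError(f"record {rec.id!r} has no species tag")
    best: dict[str, ProteinRecord] = {}
    for rec in records:
        incumbent = best.get(rec.species)
        if incumbent is None or (-rec.length, rec.id) < (
            -incumbent.length,
            incumbent.id,
        ):
            best[rec.species] = rec
    kept, dropped = [], []
    for rec in records:
        if best[rec.species] is rec:
            kept.append(rec)
        else:
            dropped.append(
                DroppedRecord(
                    rec,
                    REASON_DUPLICATE,
                    f"kept={best[rec.species].id} length={rec.length}",
                )
            )
    return kept, dropped


def _first_nongap_column(alignment: AlignmentMatrix, seq_id: str) -> int:
    row = alignment.row(seq_id)
    for col, ch in enumerate(row, start=1):
        if ch != alignment.gap_char:
            return col
    return alignment.n_columns + 1  # all-gap row


def filter_fragments(
    records: Sequence[ProteinRecord],
    alignment: Optional[AlignmentMatrix] = None,
    fragment_min_fraction: float = 0.5,
) -> tuple[list[ProteinRecord], list[DroppedRecord]]:
    """Drop short records that cover only the C-terminal part of the family.

    A record is a fragment iff its length is below ``fragment_min_fraction``
    of the median length AND, when an alignment is available, its first
    aligned (non-gap) column lies in the C-terminal half of the columns.
    Without an alignment the length criterion is applied alone, with a
    logged warning (N-terminal fragments cannot then be distinguished).
    """
    if not records:
        return [], []
    median = float(np.median([rec.length for rec in records]))
    bound = fragment_min_fraction * median
    if alignment is None:
        logger.warning(
            "fragment filter running without an alignment: using the length "
            "criterion alone (cannot verify C-terminal-only coverage)"
        )
    kept, dropped = [], []
    half_columns = alignment.n_columns / 2 if alignment is not None else 0.0
    for rec in records:
        is_short = rec.length < bound
        if is_short and alignment is not None:
            first_col = _first_nongap_column(alignment, rec.id)
            is_fragment = first_col > half_columns
            metric = f"length={rec.length} median={median:g} first_col={first_col}"
        else:
            is_fragment = is_short
            metric = f"length={rec.length} median={median:g}"
        if is_fragment:
            dropped.append(DroppedRecord(rec, REASON_FRAGMENT, metric))
        else:
            kept.append(rec)
    return kept, dropped


def filter_length_outliers(
    records: Sequence[ProteinRecord],
    length_outlier_ratio: float = 1.5,
) -> tuple[list[ProteinRecord], list[DroppedRecord]]:
    """Drop records significantly longer than the rest of the set.

    "Significantly longer" is quantified as length > ratio x median length;
    the median is computed once over the full input, before any drop.  With
    fewer than 3 records the filter passes everything through (a median over
    one or two sequences is meaningless) and warns.
    """
    if len(records) < 3:
        logger.warning(
            "length-outlier filter needs >= 3 records, got %d: passing through",
            len(records),
        )
        return list(records), []
    median = float(np.median([rec.length for rec in records]))
    bound = length_outlier_ratio * median
    kept, dropped = [], []
    for rec in records:
        if rec.length > bound:
            dropped.append(
                DroppedRecord(
                    rec, REASON_OUTLIER, f"length={rec.length} bound={bound:g}"
                )
            )
        else:
            kept.append(rec)
    return kept, dropped


def curate(
    records: Sequence[ProteinRecord],
    alignment: Optional[AlignmentMatrix] = None,
    config: Optional[AnalysisConfig] = None,
    exclude_ids: Iterable[str] = (),
) -> CurationResult:
    """Run the full filter chain in its fixed order."""
    config = config or AnalysisConfig()
    kept, dropped = apply_exclusions(records, exclude_ids)
    kept, d = dedupe_by_species(kept)
    dropped += d
    kept, d = filter_fragments(kept, alignment, config.fragment_min_fraction)
    dropped += d
    kept, d = filter_length_outliers(kept, config.length_outlier_ratio)
    dropped += d
    return CurationResult(kept=kept, dropped=dropped)


def read_exclusion_list(path: str | Path) -> list[str]:
    """One id per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def drop_report(dropped: Sequence[DroppedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"seq_id": d.record.id, "reason": d.reason, "metric": d.metric}
            for d in dropped
        ],
        columns=["seq_id", "reason", "metric"],
    )
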