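"""Core domain types and coordinate conventions.

Every residue coordinate in this package is **1-based inclusive**, matching
the convention of the protein literature (residue 1 is the N-terminal
residue; a region 146..213 contains 68 residues).  The only place 0-based
half-open coordinates appear is BED import/export, where the conversion is
``(start - 1, end)``.

The types here are deliberately small and immutable where practical; they
are shared by every pipeline stage.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in sequences: the 20 standard amino acids plus X.
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")
GAP_CHAR = "-"


class AmyconError(Exception):
    """Base class for all errors raised by this package."""


class InputFormatError(AmyconError):
    """A file could not be parsed as the expected format."""


class ConsistencyError(AmyconError):
    """Inputs parsed correctly but contradict each other or an invariant."""


class ConfigError(AmyconError):
    """A configuration value is out of its permitted range."""


class RegionLabel(str, Enum):
    """Semantic label of a :class:`Region`."""

    ARCH = "arch"
    DISORDERED = "disordered"
    AMYLOIDOGENIC = "amyloidogenic"
    CONSERVED_AMYLOID = "conserved_amyloid"
    ANNOTATION = "annotation"


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """One ungapped protein sequence with identifier and species tag.

    Parameters
    ----------
    id:
        Unique, non-empty identifier within a dataset.
    species:
        Species tag (e.g. ``Homo_sapiens``); may be ``""`` when unknown.
    sequence:
        Uppercase residue string over the 20 amino acids plus ``X``.
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ConsistencyError("protein record with empty id")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_LETTERS:
                raise InputFormatError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class Region:
    """A 1-based inclusive interval on a sequence (or on alignment columns).

    ``seq_id`` names the sequence the interval lives on; conserved-region
    calls on alignment coordinates use the sentinel id ``"alignment"``.
    """

    seq_id: str
    start: int
    end: int
    label: RegionLabel
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ConsistencyError(
                f"region on {self.seq_id!r}: invalid interval {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "Region") -> int:
        """Number of positions shared with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


class TrackKind(str, Enum):
    """Kind of per-residue score track."""

    ARCH_CUMULATIVE = "arch_cumulative"
    DISORDER = "disorder"


@dataclass(slots=True)
class ScoreTrack:
    """A per-residue real-valued track in [0, 1] attached to one sequence.

    ``values[i]`` is the score of residue ``i + 1`` (1-based).  ``provenance``
    records where the track came from (an external predictor file, the
    bundled simplified scorer, or the synthetic generator).
    """

    seq_id: str
    kind: TrackKind
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.kind = TrackKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConsistencyError(f"track for {self.seq_id!r} is not one-dimensional")
        if self.values.size and (
            float(self.values.min()) < 0.0 or float(self.values.max()) > 1.0
        ):
            bad = int(np.argmax((self.values < 0) | (self.values > 1))) + 1
            raise ConsistencyError(
                f"track for {self.seq_id!r}: score {self.values[bad - 1]:g} at "
                f"position {bad} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass(slots=True)
class AlignmentMatrix:
    """A multiple alignment: ordered gapped rows over homologous columns.

    Rows are ``(seq_id, gapped_string)`` pairs; all gapped strings have the
    same length ``n_columns``.  Removing gaps from a row must reproduce the
    corresponding :class:`ProteinRecord` sequence exactly (enforced by
    :func:`amycon.io.read_alignment`).
    """

    rows: list[tuple[str, str]]
    gap_char: str = GAP_CHAR

    def __post_init__(self) -> None:
        seen: set[str] = set()
        width = None
        for seq_id, row in self.rows:
            if seq_id in seen:
                raise ConsistencyError(f"duplicate alignment row id {seq_id!r}")
            seen.add(seq_id)
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise InputFormatError(
                    f"ragged alignment: row {seq_id!r} has length {len(row)}, "
                    f"expected {width}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [seq_id for seq_id, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, row in self.rows:
            if rid == seq_id:
                return row
        raise ConsistencyError(f"no alignment row for sequence {seq_id!r}")

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(self.gap_char, "")

    def subset(self, ids: Iterable[str]) -> "AlignmentMatrix":
        """Row subset preserving this alignment's column coordinates."""
        wanted = set(ids)
        missing = wanted - set(self.ids())
        if missing:
            raise ConsistencyError(
                f"no alignment row for sequence(s): {sorted(missing)}"
            )
        return AlignmentMatrix(
            rows=[(rid, row) for rid, row in self.rows if rid in wanted],
            gap_char=self.gap_char,
        )


def _check_unit(name: str, value: float, *, open_low: bool = False) -> None:
    lo_ok = value > 0 if open_low else value >= 0
    if not (lo_ok and value <= 1):
        bound = "(0, 1]" if open_low else "[0, 1]"
        raise ConfigError(f"{name}={value!r} outside {bound}")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the analysis, with their defaults.

    ``arch_threshold`` (0.575) and ``disorder_cutoff`` (0.3) are the
    published operating points of the upstream predictors; the remaining
    fields quantify rules the source protocol states only qualitatively and
    are this package's declared conventions (see docs/methods.md).
    """

    arch_threshold: float = 0.575
    disorder_cutoff: float = 0.3
    overlap_fraction: float = 0.5
    gap_mask_fraction: float = 0.5
    conservation_threshold: float = 0.7
    min_conserved_run: int = 5
    length_outlier_ratio: float = 1.5
    fragment_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        _check_unit("arch_threshold", self.arch_threshold)
        _check_unit("disorder_cutoff", self.disorder_cutoff)
        _check_unit("overlap_fraction", self.overlap_fraction, open_low=True)
        _check_unit("gap_mask_fraction", self.gap_mask_fraction)
        _check_unit("conservation_threshold", self.conservation_threshold)
        _check_unit("fragment_min_fraction", self.fragment_min_fraction, open_low=True)
        if self.min_conserved_run < 1:
            raise ConfigError(f"min_conserved_run={self.min_conserved_run} < 1")
        if not (self.length_outlier_ratio > 0):
            raise ConfigError(
                f"length_outlier_ratio={self.length_outlier_ratio} must be positive"
            )

    def to_dict(self) -> dict[str, float | int]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        """Build a config from string-keyed values (e.g. a parsed config file).

        Unknown keys raise :class:`ConfigError`; values are coerced from
        strings where needed.
        """
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, float | int] = {}
        for key, value in mapping.items():
            if key not in known:
                raise ConfigError(f"unknown analysis option {key!r}")
            try:
                kwargs[key] = (
                    int(str(value)) if key == "min_conserved_run" else float(str(value))
                )
            except ValueError as exc:
                raise ConfigError(f"bad value for {key!r}: {value!r}") from exc
        return cls(**kwargs)
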