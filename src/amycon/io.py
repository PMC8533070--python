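"""Readers and writers for the plain-text formats the pipeline speaks.

Formats: FASTA (sequences), aligned FASTA (multiple alignment), 3-column TSV
(per-residue score tracks), BED (regions, 0-based half-open on export only),
and a 2-column TSV sidecar mapping sequence id to species.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentMatrix,
    ConsistencyError,
    InputFormatError,
    ProteinRecord,
    Region,
    RegionLabel,
    ScoreTrack,
    TrackKind,
)

_SPECIES_TOKEN = re.compile(r"(?:^|\s)species=(\S+)")


def read_species_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (seq_id, species) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "species"],
                     dtype=str, comment="#")
    return dict(zip(df["seq_id"], df["species"]))


def read_fasta(
    path: str | Path,
    require_species: bool = False,
    species_table: Optional[Mapping[str, str]] = None,
) -> list[ProteinRecord]:
    """Read ungapped protein sequences from FASTA.

    The species tag is taken from a ``species=<tag>`` token in the header
    description, falling back to ``species_table`` when given.  Duplicate
    ids, non-amino-acid characters, and (if ``require_species``) unresolved
    species are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ConsistencyError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        match = _SPECIES_TOKEN.search(entry.description)
        species = match.group(1) if match else ""
        if not species and species_table:
            species = species_table.get(entry.id, "")
        if require_species and not species:
            raise ConsistencyError(
                f"no species resolvable for sequence {entry.id!r}"
            )
        seq = str(entry.seq).upper()
        if "-" in seq:
            raise InputFormatError(
                f"record {entry.id!r}: gap character in ungapped FASTA "
                f"at position {seq.index('-') + 1}"
            )
        records.append(ProteinRecord(id=entry.id, species=species, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with ``species=`` header tokens."""
    entries = []
    for rec in records:
        desc = f"species={rec.species}" if rec.species else ""
        entries.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(entries, str(path), "fasta")


def read_alignment(
    path: str | Path, records: Sequence[ProteinRecord]
) -> AlignmentMatrix:
    """Read an aligned FASTA and validate it against ``records``.

    Every row id must match a record id and every degapped row must equal
    the record sequence exactly; the first differing residue index is
    reported on mismatch.
    """
    by_id = {rec.id: rec for rec in records}
    rows: list[tuple[str, str]] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        row = str(entry.seq).upper()
        rows.append((entry.id, row))
    matrix = AlignmentMatrix(rows=rows)
    validate_alignment(matrix, by_id)
    return matrix


def validate_alignment(
    matrix: AlignmentMatrix, by_id: Mapping[str, ProteinRecord]
) -> None:
    """Check degapped rows against record sequences (see read_alignment)."""
    for seq_id, row in matrix.rows:
        if seq_id not in by_id:
            raise ConsistencyError(f"alignment row {seq_id!r} has no record")
        degapped = row.replace(matrix.gap_char, "")
        expected = by_id[seq_id].sequence
        if degapped != expected:
            limit = min(len(degapped), len(expected))
            idx = next(
                (i for i in range(limit) if degapped[i] != expected[i]), limit
            )
            raise ConsistencyError(
                f"alignment row {seq_id!r} disagrees with its sequence at "
                f"residue {idx + 1}"
            )


def write_alignment(matrix: AlignmentMatrix, path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(row), id=seq_id, description="") for seq_id, row in matrix.rows
    ]
    SeqIO.write(entries, str(path), "fasta")


_SCORE_COLUMNS = ["seq_id", "position", "score"]


def read_score_table(path: str | Path, kind: TrackKind | str) -> list[ScoreTrack]:
    """Read per-residue scores from a 3-column TSV (seq_id, position, score).

    Positions are 1-based and must cover ``1..length`` contiguously for each
    sequence; scores outside [0, 1] are rejected, not clipped.
    """
    kind = TrackKind(kind)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                     names=_SCORE_COLUMNS)
    if len(df) and df.iloc[0]["seq_id"] == "seq_id":
        df = df.iloc[1:].reset_index(drop=True)
    if not len(df):
        return []
    try:
        positions = df["position"].astype(int)
        scores = df["score"].astype(float)
    except ValueError as exc:
        raise InputFormatError(f"non-numeric field in score table {path}: {exc}")
    df = pd.DataFrame(
        {"seq_id": df["seq_id"], "position": positions, "score": scores}
    )
    tracks: list[ScoreTrack] = []
    for seq_id in df["seq_id"].unique():
        sub = df[df["seq_id"] == seq_id]
        bad = sub[(sub["score"] < 0) | (sub["score"] > 1)]
        if len(bad):
            row = bad.iloc[0]
            raise ConsistencyError(
                f"score {row['score']:g} for {seq_id!r} position "
                f"{int(row['position'])} outside [0, 1]"
            )
        present = set(sub["position"].tolist())
        top = max(present)
        for pos in range(1, top + 1):
            if pos not in present:
                raise ConsistencyError(
                    f"score table missing position {pos} for sequence {seq_id!r}"
                )
        if len(sub) != top:
            dup = sub["position"][sub["position"].duplicated()].iloc[0]
            raise ConsistencyError(
                f"duplicate position {int(dup)} for sequence {seq_id!r}"
            )
        values = np.empty(top, dtype=float)
        values[sub["position"].to_numpy() - 1] = sub["score"].to_numpy()
        tracks.append(
            ScoreTrack(seq_id=str(seq_id), kind=kind, values=values,
                       provenance="external")
        )
    return tracks


def write_score_table(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    """Write tracks to the 3-column TSV; provenance goes in a comment line."""
    tracks = list(tracks)
    with open(path, "w") as fh:
        provenances = sorted({t.provenance for t in tracks if t.provenance})
        if provenances:
            fh.write(f"# provenance: {', '.join(provenances)}\n")
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for track in tracks:
            for pos, value in enumerate(track.values, start=1):
                fh.write(f"{track.seq_id}\t{pos}\t{value:.6g}\n")


def attach_tracks(
    records: Sequence[ProteinRecord], tracks: Sequence[ScoreTrack]
) -> dict[str, ScoreTrack]:
    """Index tracks by sequence id, validating lengths against records."""
    by_id = {rec.id: rec for rec in records}
    out: dict[str, ScoreTrack] = {}
    for track in tracks:
        if track.seq_id not in by_id:
            raise ConsistencyError(f"track for unknown sequence {track.seq_id!r}")
        expected = by_id[track.seq_id].length
        if track.length != expected:
            raise ConsistencyError(
                f"track for {track.seq_id!r} has {track.length} values, "
                f"sequence has {expected} residues"
            )
        out[track.seq_id] = track
    return out


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as 5-column BED (0-based half-open, score in 0..1000)."""
    with open(path, "w") as fh:
        for region in regions:
            score = 0 if region.score is None else int(round(region.score * 1000))
            score = min(1000, max(0, score))
            fh.write(
                f"{region.seq_id}\t{region.start - 1}\t{region.end}\t"
                f"{region.label.value}\t{score}\n"
            )


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read 5-column BED back into 1-based inclusive regions."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputFormatError(f"{path}:{lineno}: expected ≥4 BED columns")
            seq_id, start, end, label = parts[:4]
            score = int(parts[4]) / 1000 if len(parts) > 4 else None
            regions.append(
                Region(
                    seq_id=seq_id,
                    start=int(start) + 1,
                    end=int(end),
                    label=RegionLabel(label),
                    score=score,
                )
            )
    return regions
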