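"""Synthetic ortholog families with known amyloid ground truth.

The generator emulates the input of a nucleoporin-style conservation
analysis: a family of mostly-disordered orthologs sharing conserved
amyloidogenic motifs, contaminated with the curation targets a real
database export contains (same-species duplicates, a C-terminal fragment,
an over-long sequence).

Model
-----
One ancestral sequence of length ``seq_length`` is drawn from a
disorder-biased background alphabet (G/S/Q/N/E/K/P-rich) with FG
dipeptides interspersed outside motifs, and aggregation-prone motifs
(Q/N/hydrophobic-rich) implanted at the positions in ``motifs``.  Each of
``n_species`` descendants evolves independently from the ancestor (star
phylogeny): substitutions at per-site probability ``p_sub_background``
outside motifs (drawn from the background distribution) and
``p_sub_motif`` inside motifs (drawn within the aggregation-prone class,
so amyloid propensity is conserved even where identity is not); indels at
per-site probability ``p_indel`` strictly outside motifs, so each truth
region stays one contiguous interval.  Because every residue's homology to
an ancestral coordinate is recorded during descent, the true multiple
alignment is available by construction: one column per ancestral position
plus private columns for each insertion.

All randomness flows through one ``numpy.random.default_rng(seed)``; a
fixed seed reproduces the family byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AlignmentMatrix,
    ConfigError,
    ProteinRecord,
    Region,
    RegionLabel,
    ScoreTrack,
    TrackKind,
)
from .curation import REASON_DUPLICATE, REASON_FRAGMENT, REASON_OUTLIER

# Background (disorder-biased) residue frequencies.
_BACKGROUND = {
    "G": 0.14, "S": 0.14, "Q": 0.10, "N": 0.08, "E": 0.12, "K": 0.10,
    "P": 0.10, "T": 0.06, "A": 0.06, "D": 0.05, "R": 0.05,
}
# Aggregation-prone motif residue frequencies (amide/hydrophobic class).
_MOTIF = {
    "Q": 0.22, "N": 0.22, "V": 0.10, "I": 0.10, "L": 0.08, "F": 0.08,
    "Y": 0.06, "S": 0.08, "T": 0.06,
}
#: Spacing of implanted FG dipeptides in the ancestral background.
_FG_STRIDE = 25

# Synthetic score-track levels (stand-ins for external predictor output).
ARCH_IN_REGION = 0.8
ARCH_BACKGROUND = 0.3
DISORDER_LEVEL = 0.6
ORDERED_STUB_LEVEL = 0.2
ORDERED_STUB_LEN = 50


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic ortholog family (defaults = study scale)."""

    n_species: int = 20
    seq_length: int = 600
    motifs: tuple[tuple[int, int], ...] = ((150, 60), (320, 40))
    p_sub_background: float = 0.3
    p_sub_motif: float = 0.1
    p_indel: float = 0.02
    max_indel_len: int = 5
    duplicate_species: int = 2
    fragment_count: int = 1
    outlier_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_sub_background, self.p_sub_motif, self.p_indel):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")
        spans = []
        for start, length in self.motifs:
            end = start + length - 1
            if start < 1 or end > self.seq_length:
                raise ConfigError(
                    f"motif ({start},{length}) outside 1..{self.seq_length}"
                )
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("motifs overlap")


@dataclass
class _Descendant:
    """Homology bookkeeping for one simulated sequence."""

    residue_at: dict[int, str]       # kept ancestral position -> residue
    ins_after: dict[int, str]        # ancestral position -> inserted residues

    def sequence(self, length: int) -> str:
        parts = []
        for p in range(1, length + 1):
            r = self.residue_at.get(p)
            if r is not None:
                parts.append(r)
            ins = self.ins_after.get(p)
            if ins:
                parts.append(ins)
        return "".join(parts)


@dataclass
class FamilyTruth:
    """Ground truth attached to a simulated family."""

    #: seq_id -> true amyloidogenic regions (sequence coordinates).
    regions: dict[str, list[Region]]
    #: per alignment column (0-based list): homologous ancestral position,
    #: or None for an insertion column.
    column_homology: list[Optional[int]]
    #: 1-based alignment columns homologous to motif positions.
    conserved_columns: list[int]
    #: seq_id -> curation reason code for the injected removable records.
    injected_drops: dict[str, str] = field(default_factory=dict)


def _sampler(table: dict[str, float]):
    letters = np.array(list(table), dtype="<U1")
    probs = np.array(list(table.values()), dtype=float)
    probs = probs / probs.sum()
    return letters, probs


def _sample_ancestor(rng: np.random.Generator, spec: FamilySpec) -> tuple[str, np.ndarray]:
    """Ancestral sequence and a boolean motif mask (index 0 = position 1)."""
    letters, probs = _sampler(_BACKGROUND)
    seq = list(rng.choice(letters, size=spec.seq_length, p=probs))
    motif_mask = np.zeros(spec.seq_length + 1, dtype=bool)  # 1-based
    for start, length in spec.motifs:
        motif_mask[start : start + length] = True
    # FG dipeptides interspersed in the background
    for p in range(10, spec.seq_length - 1, _FG_STRIDE):
        if not motif_mask[p] and not motif_mask[p + 1]:
            seq[p - 1] = "F"
            seq[p] = "G"
    m_letters, m_probs = _sampler(_MOTIF)
    for start, length in spec.motifs:
        block = rng.choice(m_letters, size=length, p=m_probs)
        seq[start - 1 : start + length - 1] = list(block)
    return "".join(seq), motif_mask


def _descend(
    rng: np.random.Generator,
    ancestor: str,
    motif_mask: np.ndarray,
    spec: FamilySpec,
    with_indels: bool = True,
) -> _Descendant:
    bg_letters, bg_probs = _sampler(_BACKGROUND)
    m_letters, m_probs = _sampler(_MOTIF)
    length = len(ancestor)
    residue_at: dict[int, str] = {}
    ins_after: dict[int, str] = {}
    p_event = spec.p_indel / 2 if with_indels else 0.0
    p = 1
    while p <= length:
        if motif_mask[p]:
            r = ancestor[p - 1]
            if rng.random() < spec.p_sub_motif:
                r = str(rng.choice(m_letters, p=m_probs))
            residue_at[p] = r
            p += 1
            continue
        if with_indels and rng.random() < p_event:
            # deletion starting here; never eats into a motif
            d = int(rng.integers(1, spec.max_indel_len + 1))
            while d > 0 and p <= length and not motif_mask[p]:
                p += 1
                d -= 1
            continue
        r = ancestor[p - 1]
        if rng.random() < spec.p_sub_background:
            r = str(rng.choice(bg_letters, p=bg_probs))
        residue_at[p] = r
        if with_indels and rng.random() < p_event:
            k = int(rng.integers(1, spec.max_indel_len + 1))
            ins_after[p] = "".join(rng.choice(bg_letters, size=k, p=bg_probs))
        p += 1
    return _Descendant(residue_at=residue_at, ins_after=ins_after)


def _truth_regions(
    seq_id: str, desc: _Descendant, spec: FamilySpec
) -> list[Region]:
    """Map each fully-covered motif into the descendant's own coordinates."""
    kept = sorted(desc.residue_at)
    out: list[Region] = []
    offset = 0
    pos_of: dict[int, int] = {}
    for p in kept:
        offset += 1
        pos_of[p] = offset
        offset += len(desc.ins_after.get(p, ""))
    for start, length in spec.motifs:
        anc_end = start + length - 1
        if start in pos_of and anc_end in pos_of:
            out.append(
                Region(seq_id, pos_of[start], pos_of[anc_end],
                       RegionLabel.AMYLOIDOGENIC)
            )
    return out


def simulate_family(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], AlignmentMatrix, FamilyTruth]:
    """Simulate one family: records, true alignment, and ground truth.

    Row/record order: the ``n_species`` descendants, then duplicates,
    fragments, and over-long outliers.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor, motif_mask = _sample_ancestor(rng, spec)
    length = spec.seq_length

    names: list[tuple[str, str]] = []  # (seq_id, species)
    descendants: list[_Descendant] = []
    for i in range(1, spec.n_species + 1):
        names.append((f"seq{i:02d}", f"species_{i:02d}"))
        descendants.append(_descend(rng, ancestor, motif_mask, spec))

    injected: dict[str, str] = {}

    # same-species duplicates: substitutions-only copies truncated by 10%
    cutoff = int(0.9 * length)
    for j in range(spec.duplicate_species):
        parent_idx = j % spec.n_species
        seq_id = f"{names[parent_idx][0]}_dup"
        desc = _descend(rng, ancestor, motif_mask, spec, with_indels=False)
        desc.residue_at = {p: r for p, r in desc.residue_at.items() if p <= cutoff}
        desc.ins_after = {}
        names.append((seq_id, names[parent_idx][1]))
        descendants.append(desc)
        injected[seq_id] = REASON_DUPLICATE

    # C-terminal fragments: last 30% of a substitutions-only descendant
    frag_from = length - int(0.3 * length) + 1
    for j in range(1, spec.fragment_count + 1):
        seq_id = f"frag{j:02d}"
        desc = _descend(rng, ancestor, motif_mask, spec, with_indels=False)
        desc.residue_at = {
            p: r for p, r in desc.residue_at.items() if p >= frag_from
        }
        desc.ins_after = {}
        names.append((seq_id, f"species_frag{j:02d}"))
        descendants.append(desc)
        injected[seq_id] = REASON_FRAGMENT

    # over-long outliers: full descendant plus a long internal disordered
    # expansion (inserted after the ordered stub, ahead of the first motif)
    bg_letters, bg_probs = _sampler(_BACKGROUND)
    extra_len = int(0.8 * length)
    for j in range(1, spec.outlier_count + 1):
        seq_id = f"long{j:02d}"
        desc = _descend(rng, ancestor, motif_mask, spec, with_indels=False)
        desc.ins_after = {
            ORDERED_STUB_LEN: "".join(
                rng.choice(bg_letters, size=extra_len, p=bg_probs)
            )
        }
        names.append((seq_id, f"species_long{j:02d}"))
        descendants.append(desc)
        injected[seq_id] = REASON_OUTLIER

    records = [
        ProteinRecord(id=seq_id, species=species,
                      sequence=desc.sequence(length))
        for (seq_id, species), desc in zip(names, descendants)
    ]

    # --- true alignment: ancestral columns + private insertion columns ---
    gap = "-"
    row_chunks: list[list[str]] = [[] for _ in names]
    column_homology: list[Optional[int]] = []
    for p in range(1, length + 1):
        for chunks, desc in zip(row_chunks, descendants):
            chunks.append(desc.residue_at.get(p, gap))
        column_homology.append(p)
        for i, desc in enumerate(descendants):
            ins = desc.ins_after.get(p, "")
            if ins:
                for chunks_j in row_chunks:
                    chunks_j.append(gap * len(ins))
                row_chunks[i][-1] = ins
                column_homology.extend([None] * len(ins))
    alignment = AlignmentMatrix(
        rows=[
            (seq_id, "".join(chunks))
            for (seq_id, _), chunks in zip(names, row_chunks)
        ]
    )

    conserved_columns = [
        c + 1
        for c, h in enumerate(column_homology)
        if h is not None and motif_mask[h]
    ]
    truth = FamilyTruth(
        regions={
            seq_id: _truth_regions(seq_id, desc, spec)
            for (seq_id, _), desc in zip(names, descendants)
        },
        column_homology=column_homology,
        conserved_columns=conserved_columns,
        injected_drops=injected,
    )
    return records, alignment, truth


def simulate_tracks(
    records: Sequence[ProteinRecord],
    truth: FamilyTruth,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[ScoreTrack], list[ScoreTrack]]:
    """Synthetic predictor output for a simulated family.

    The arch track is ``ARCH_IN_REGION`` (0.8) inside truth regions and
    ``ARCH_BACKGROUND`` (0.3) outside; the disorder track is
    ``DISORDER_LEVEL`` (0.6) everywhere except an ordered stub over the
    first ``ORDERED_STUB_LEN`` residues at ``ORDERED_STUB_LEVEL`` (0.2).
    Gaussian noise of the given sd is added and values clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    arch_tracks: list[ScoreTrack] = []
    dis_tracks: list[ScoreTrack] = []
    for rec in records:
        in_region = np.zeros(rec.length, dtype=bool)
        for region in truth.regions.get(rec.id, ()):
            in_region[region.start - 1 : region.end] = True
        arch = np.where(in_region, ARCH_IN_REGION, ARCH_BACKGROUND)
        dis = np.full(rec.length, DISORDER_LEVEL)
        dis[: min(ORDERED_STUB_LEN, rec.length)] = ORDERED_STUB_LEVEL
        if noise_sd > 0:
            arch = arch + rng.normal(0.0, noise_sd, rec.length)
            dis = dis + rng.normal(0.0, noise_sd, rec.length)
        arch_tracks.append(
            ScoreTrack(rec.id, TrackKind.ARCH_CUMULATIVE,
                       np.clip(arch, 0.0, 1.0), provenance="synthetic")
        )
        dis_tracks.append(
            ScoreTrack(rec.id, TrackKind.DISORDER,
                       np.clip(dis, 0.0, 1.0), provenance="synthetic")
        )
    return arch_tracks, dis_tracks


def write_truth(truth: FamilyTruth, regions_path, columns_path) -> None:
    """Write truth regions and truth columns as TSV."""
    with open(regions_path, "w") as fh:
        fh.write("seq_id\tstart\tend\n")
        for seq_id in truth.regions:
            for region in truth.regions[seq_id]:
                fh.write(f"{seq_id}\t{region.start}\t{region.end}\n")
    conserved = set(truth.conserved_columns)
    with open(columns_path, "w") as fh:
        fh.write("column\thomology\tis_conserved\n")
        for c, h in enumerate(truth.column_homology, start=1):
            fh.write(f"{c}\t{'' if h is None else h}\t{int(c in conserved)}\n")
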