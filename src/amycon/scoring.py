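"""Bundled stand-in scorers for beta-arch and disorder propensity.

Real analyses of this kind run dedicated external predictors (a beta-arch
scanner for amyloidogenicity, a pairwise-energy disorder predictor) and feed
their per-residue outputs into the pipeline as score tables.  The scorers in
this module are deliberately **simplified stand-ins**: a propensity-scale
window scanner for strand-loop-strand (beta-arch) motifs and a windowed-mean
disorder profile.  They exist so the whole pipeline runs and is testable
with no external binaries; every track they emit carries the provenance tag
``"standin-simplified"`` so downstream reports can distinguish them from
external predictor output.

Model
-----
A beta-arch candidate is a strand-loop-strand window: two strands of 4..9
residues flanking a loop of 1..15 residues.  Its raw score is the mean
propensity-scale value over the two strands minus a proline penalty (0.5
per strand proline — proline is a strong beta-strand breaker), squashed to
[0, 1] with a logistic centred at ``_LOGISTIC_MU`` with width
``_LOGISTIC_S``.  The per-residue "cumulative" track is the maximum
normalized score over all candidates covering the residue, which preserves
the at-least-one-arch semantics of the downstream amyloid call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    AMINO_ACIDS,
    ConfigError,
    ConsistencyError,
    ProteinRecord,
    Region,
    RegionLabel,
    ScoreTrack,
    TrackKind,
)

#: Logistic normalization constants for the arch raw score.  Chosen so that
#: strands drawn from the amide/hydrophobic end of the shipped scale (raw
#: about 0.8) normalize well above the published 0.575 operating point while
#: acidic or proline-rich strands normalize near zero.
_LOGISTIC_MU = 0.60
_LOGISTIC_S = 0.08
#: Raw-score penalty per proline residue inside a strand.
_PROLINE_PENALTY = 0.5

DEFAULT_STRAND_LEN = (4, 9)
DEFAULT_LOOP_LEN = (1, 15)
STANDIN_PROVENANCE = "standin-simplified"


@dataclass(frozen=True)
class PropensityScale:
    """Per-letter propensity values for the 20 amino acids plus X."""

    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = set(AMINO_ACIDS + "X")
        got = set(self.values)
        if got != expected:
            raise ConfigError(
                f"propensity scale must define exactly {sorted(expected)}; "
                f"missing {sorted(expected - got)}, extra {sorted(got - expected)}"
            )
        for letter, value in self.values.items():
            if not np.isfinite(value):
                raise ConfigError(f"non-finite propensity for {letter!r}")

    def as_array(self) -> np.ndarray:
        """Values indexed by ASCII code (for vectorized lookup)."""
        arr = np.zeros(128, dtype=float)
        for letter, value in self.values.items():
            arr[ord(letter)] = value
        return arr


def load_scale(which: str | Path) -> PropensityScale:
    """Load a bundled scale (``"beta_arch"`` / ``"disorder"``) or a file.

    Files are 2-column whitespace-separated text: letter, value; ``#``
    comments allowed.
    """
    bundled = {
        "beta_arch": "beta_arch_propensity.tsv",
        "disorder": "disorder_propensity.tsv",
    }
    if str(which) in bundled:
        ref = resources.files("amycon.data") / bundled[str(which)]
        text = ref.read_text()
        provenance = f"bundled:{bundled[str(which)]}"
    else:
        text = Path(which).read_text()
        provenance = f"file:{which}"
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split()
        values[letter] = float(value)
    return PropensityScale(values=values, provenance=provenance)


@dataclass(frozen=True, slots=True)
class ArchCandidate:
    """One strand-loop-strand window with its raw and normalized score."""

    seq_id: str
    strand1: Region
    strand2: Region
    loop: Region
    raw_score: float
    norm_score: float

    def __post_init__(self) -> None:
        ok = (
            self.strand1.end < self.loop.start <= self.loop.end < self.strand2.start
            and self.loop.start == self.strand1.end + 1
            and self.strand2.start == self.loop.end + 1
        )
        if not ok:
            raise ConsistencyError(
                f"arch candidate on {self.seq_id!r}: strands not contiguous "
                f"with loop"
            )

    @property
    def start(self) -> int:
        return self.strand1.start

    @property
    def end(self) -> int:
        return self.strand2.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _logistic(raw: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(raw - _LOGISTIC_MU) / _LOGISTIC_S))


def scan_arches(
    record: ProteinRecord,
    scale: Optional[PropensityScale] = None,
    strand_len: tuple[int, int] = DEFAULT_STRAND_LEN,
    loop_len: tuple[int, int] = DEFAULT_LOOP_LEN,
) -> list[ArchCandidate]:
    """Exhaustively enumerate and score strand-loop-strand windows.

    Returns candidates sorted by decreasing normalized score, ties broken by
    (start, span).  A sequence too short for even the smallest window yields
    an empty list.
    """
    if scale is None:
        scale = load_scale("beta_arch")
    codes = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    length = codes.size
    vals = scale.as_array()[codes]
    is_pro = (codes == ord("P")).astype(float)
    # prefix sums for O(1) window sums
    cum_vals = np.concatenate([[0.0], np.cumsum(vals)])
    cum_pro = np.concatenate([[0.0], np.cumsum(is_pro)])
    s_lo, s_hi = strand_len
    l_lo, l_hi = loop_len
    out: list[ArchCandidate] = []
    for s1 in range(s_lo, s_hi + 1):
        for lp in range(l_lo, l_hi + 1):
            for s2 in range(s_lo, s_hi + 1):
                total = s1 + lp + s2
                n_pos = length - total + 1
                if n_pos <= 0:
                    continue
                i = np.arange(n_pos)  # 0-based window starts
                sum1 = cum_vals[i + s1] - cum_vals[i]
                pro1 = cum_pro[i + s1] - cum_pro[i]
                j = i + s1 + lp  # 0-based strand2 starts
                sum2 = cum_vals[j + s2] - cum_vals[j]
                pro2 = cum_pro[j + s2] - cum_pro[j]
                raw = (sum1 + sum2) / (s1 + s2) - _PROLINE_PENALTY * (pro1 + pro2)
                norm = _logistic(raw)
                for k in range(n_pos):
                    start = int(i[k]) + 1
                    out.append(
                        ArchCandidate(
                            seq_id=record.id,
                            strand1=Region(record.id, start, start + s1 - 1,
                                           RegionLabel.ARCH),
                            loop=Region(record.id, start + s1,
                                        start + s1 + lp - 1, RegionLabel.ARCH),
                            strand2=Region(record.id, start + s1 + lp,
                                           start + total - 1, RegionLabel.ARCH),
                            raw_score=float(raw[k]),
                            norm_score=float(norm[k]),
                        )
                    )
    out.sort(key=lambda c: (-c.norm_score, c.start, c.span))
    return out


def cumulative_track(
    candidates: Sequence[ArchCandidate], length: int, seq_id: str
) -> ScoreTrack:
    """Per-residue maximum normalized score over all covering candidates.

    Residues covered by no candidate score 0.
    """
    values = np.zeros(length, dtype=float)
    for cand in candidates:
        if cand.start < 1 or cand.end > length:
            raise ConsistencyError(
                f"candidate {cand.start}..{cand.end} outside 1..{length} "
                f"on {seq_id!r}"
            )
        lo, hi = cand.start - 1, cand.end
        np.maximum(values[lo:hi], cand.norm_score, out=values[lo:hi])
    return ScoreTrack(seq_id=seq_id, kind=TrackKind.ARCH_CUMULATIVE,
                      values=values, provenance=STANDIN_PROVENANCE)


def disorder_track(
    record: ProteinRecord,
    scale: Optional[PropensityScale] = None,
    window: int = 21,
) -> ScoreTrack:
    """Windowed-mean disorder propensity, min-max rescaled per sequence.

    The window is centred on each residue and truncated at the termini.  A
    compositionally constant profile rescales to a flat 0.5.  The published
    0.3 disorder cutoff is applied downstream on this rescaled track.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"disorder window must be odd and >= 1, got {window}")
    if scale is None:
        scale = load_scale("disorder")
    codes = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    vals = scale.as_array()[codes]
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(codes.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, codes.size)
    means = (cum[hi] - cum[lo]) / (hi - lo)
    span = float(means.max() - means.min()) if means.size else 0.0
    if span > 1e-12:
        rescaled = (means - means.min()) / span
    else:
        rescaled = np.full_like(means, 0.5)
    return ScoreTrack(seq_id=record.id, kind=TrackKind.DISORDER,
                      values=rescaled, provenance=STANDIN_PROVENANCE)


def standin_tracks(
    records: Iterable[ProteinRecord],
    window: int = 21,
) -> tuple[list[ScoreTrack], list[ScoreTrack]]:
    """Run both stand-in scorers over a set of records.

    Returns (arch_cumulative tracks, disorder tracks), one per record.
    """
    arch_scale = load_scale("beta_arch")
    dis_scale = load_scale("disorder")
    arch_tracks: list[ScoreTrack] = []
    dis_tracks: list[ScoreTrack] = []
    for rec in records:
        cands = scan_arches(rec, arch_scale)
        arch_tracks.append(cumulative_track(cands, rec.length, rec.id))
        dis_tracks.append(disorder_track(rec, dis_scale, window=window))
    return arch_tracks, dis_tracks
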