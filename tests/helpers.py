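"""Independent brute-force oracles and generators shared across tests.

Everything here is deliberately naive (per-residue booleans, python loops)
so it cannot share a bug with the vectorized implementations it checks.
"""

from __future__ import annotations

import numpy as np

from amycon.model import AlignmentMatrix, Region, RegionLabel

AA = "ACDEFGHIKLMNPQRSTVWY"


def regions_to_mask(regions, length: int) -> list[bool]:
    mask = [False] * length
    for region in regions:
        for pos in range(region.start, region.end + 1):
            mask[pos - 1] = True
    return mask


def mask_to_runs(mask) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based (start, end), by linear scan."""
    runs = []
    start = None
    for i, flag in enumerate(mask, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def oracle_disordered(values, cutoff) -> list[tuple[int, int]]:
    return mask_to_runs([v > cutoff for v in values])


def oracle_arch_track(values, threshold) -> list[tuple[int, int]]:
    return mask_to_runs([v >= threshold for v in values])


def oracle_amyloidogenic(arch_runs, disordered_runs, overlap_fraction, length):
    """Retained-arch residue mask via per-residue counting, then run scan."""
    dis_mask = regions_to_mask(
        [Region("x", s, e, RegionLabel.DISORDERED) for s, e in disordered_runs],
        length,
    )
    out_mask = [False] * length
    for s, e in arch_runs:
        inside = sum(dis_mask[p - 1] for p in range(s, e + 1))
        if inside / (e - s + 1) >= overlap_fraction:
            for p in range(s, e + 1):
                out_mask[p - 1] = True
    return mask_to_runs(out_mask)


def oracle_column_amyloid_fraction(matrix: AlignmentMatrix, regions_by_seq):
    """Rasterize regions per sequence, walk every row residue by residue."""
    n = matrix.n_columns
    nongap = [0] * n
    amyl = [0] * n
    for seq_id, row in matrix.rows:
        length = len(row) - row.count(matrix.gap_char)
        mask = regions_to_mask(regions_by_seq.get(seq_id, ()), length)
        res = 0
        for col, ch in enumerate(row):
            if ch != matrix.gap_char:
                nongap[col] += 1
                if mask[res]:
                    amyl[col] += 1
                res += 1
    return [a / g if g else 0.0 for a, g in zip(amyl, nongap)]


def oracle_conserved_runs(fractions, masked, threshold, min_run):
    ok = [f >= threshold and not m for f, m in zip(fractions, masked)]
    return [(s, e) for s, e in mask_to_runs(ok) if e - s + 1 >= min_run]


def regions_as_tuples(regions) -> list[tuple[int, int]]:
    return [(r.start, r.end) for r in regions]


def region_columns(regions) -> set[int]:
    cols: set[int] = set()
    for region in regions:
        cols.update(range(region.start, region.end + 1))
    return cols


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def random_alignment(rng: np.random.Generator, n_rows: int, n_cols: int,
                     p_gap: float = 0.3) -> AlignmentMatrix:
    """Random gapped rows; every row is guaranteed >= 1 residue."""
    rows = []
    letters = np.array(list(AA))
    for i in range(n_rows):
        gaps = rng.random(n_cols) < p_gap
        if gaps.all():
            gaps[rng.integers(n_cols)] = False
        chars = rng.choice(letters, size=n_cols)
        row = "".join("-" if g else c for g, c in zip(gaps, chars))
        rows.append((f"r{i}", row))
    return AlignmentMatrix(rows=rows)


def random_regions(rng: np.random.Generator, seq_id: str, length: int,
                   max_regions: int = 4) -> list[Region]:
    out = []
    for _ in range(rng.integers(0, max_regions + 1)):
        start = int(rng.integers(1, length + 1))
        end = int(min(length, start + rng.integers(0, max(2, length // 3))))
        out.append(Region(seq_id, start, end, RegionLabel.AMYLOIDOGENIC))
    return out
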