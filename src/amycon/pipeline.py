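"""End-to-end orchestration: curation -> region calling -> projection -> report.

`run_pipeline` is the library entry point the CLI wraps; it takes in-memory
objects so tests and the synthetic generator can drive it directly.
`write_outputs` materializes a result as the plain-text output tree (BED,
TSV, manifest, optional heatmap).
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .conserved import (
    back_project_regions,
    call_conserved_amyloid_regions,
    conservation_contrast,
)
from .curation import CurationResult, curate, drop_report
from .io import attach_tracks, write_regions_bed
from .model import (
    AlignmentMatrix,
    AnalysisConfig,
    ConfigError,
    ConsistencyError,
    ProteinRecord,
    Region,
    ScoreTrack,
)
from .projection import ColumnProfile, build_profile
from .regions import (
    call_amyloidogenic_regions,
    call_arch_regions,
    call_disordered_segments,
    summarize_amyloidogenicity,
)

logger = logging.getLogger(__name__)

#: Thresholds with a published source; everything else is a package default.
PUBLISHED_DEFAULTS = {"arch_threshold": 0.575, "disorder_cutoff": 0.3}


@dataclass
class PipelineResult:
    kept_records: list[ProteinRecord]
    curation: CurationResult
    alignment: AlignmentMatrix
    disordered_by_seq: dict[str, list[Region]]
    arch_by_seq: dict[str, list[Region]]
    amyloid_by_seq: dict[str, list[Region]]
    summary: pd.DataFrame
    profile: ColumnProfile
    conserved_regions: list[Region]
    contrast: pd.DataFrame
    back_projected: dict[str, list[Region]]


def run_pipeline(
    records: Sequence[ProteinRecord],
    alignment: AlignmentMatrix,
    arch_tracks: Sequence[ScoreTrack],
    disorder_tracks: Sequence[ScoreTrack],
    config: Optional[AnalysisConfig] = None,
    exclude_ids: Iterable[str] = (),
) -> PipelineResult:
    """Run curation, region calling, projection, and conserved-region calling.

    The surviving rows keep their original alignment columns (no
    realignment happens here); columns left all-gap by dropped rows are
    masked in the profile.
    """
    config = config or AnalysisConfig()
    logger.info("[curate] %d records in", len(records))
    curation = curate(records, alignment, config, exclude_ids)
    kept = curation.kept
    logger.info("[curate] kept %d, dropped %d", len(kept), len(curation.dropped))
    if not kept:
        raise ConsistencyError("curation removed every record")
    sub_alignment = alignment.subset([rec.id for rec in kept])

    arch_by_id = attach_tracks(records, arch_tracks)
    dis_by_id = attach_tracks(records, disorder_tracks)
    disordered_by_seq: dict[str, list[Region]] = {}
    arch_by_seq: dict[str, list[Region]] = {}
    amyloid_by_seq: dict[str, list[Region]] = {}
    for rec in kept:
        if rec.id not in arch_by_id or rec.id not in dis_by_id:
            raise ConsistencyError(f"no score tracks for sequence {rec.id!r}")
        disordered = call_disordered_segments(
            dis_by_id[rec.id], config.disorder_cutoff
        )
        arch = call_arch_regions(arch_by_id[rec.id], config.arch_threshold)
        amyloid = call_amyloidogenic_regions(
            arch, disordered, config.overlap_fraction
        )
        disordered_by_seq[rec.id] = disordered
        arch_by_seq[rec.id] = arch
        amyloid_by_seq[rec.id] = amyloid
    summary = summarize_amyloidogenicity(amyloid_by_seq)
    logger.info(
        "[call] %d/%d potential amyloids",
        int(summary["is_potential_amyloid"].sum()), len(kept),
    )

    profile = build_profile(sub_alignment, amyloid_by_seq, config)
    conserved = call_conserved_amyloid_regions(
        profile, config.conservation_threshold, config.min_conserved_run
    )
    logger.info("[conserved] %d region(s)", len(conserved))
    contrast = conservation_contrast(profile, conserved)
    back_projected = back_project_regions(sub_alignment, conserved)
    return PipelineResult(
        kept_records=kept,
        curation=curation,
        alignment=sub_alignment,
        disordered_by_seq=disordered_by_seq,
        arch_by_seq=arch_by_seq,
        amyloid_by_seq=amyloid_by_seq,
        summary=summary,
        profile=profile,
        conserved_regions=conserved,
        contrast=contrast,
        back_projected=back_projected,
    )


def _format_contrast(contrast: pd.DataFrame) -> pd.DataFrame:
    out = contrast.copy()
    for col in ("mean_amyloid_fraction", "mean_identity", "difference"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    return out


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    config: AnalysisConfig,
    seed: Optional[int] = None,
    provenance: str = "",
    heatmap: bool = True,
) -> Path:
    """Write the full plain-text output tree for a pipeline result."""
    outdir = Path(outdir)
    (outdir / "regions").mkdir(parents=True, exist_ok=True)

    for rec in result.kept_records:
        regions = (
            result.disordered_by_seq.get(rec.id, [])
            + result.arch_by_seq.get(rec.id, [])
            + result.amyloid_by_seq.get(rec.id, [])
        )
        write_regions_bed(regions, outdir / "regions" / f"{rec.id}.bed")
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    result.profile.write_tsv(outdir / "profile.tsv")
    write_regions_bed(result.conserved_regions, outdir / "conserved_regions.bed")
    _format_contrast(result.contrast).to_csv(
        outdir / "conserved_regions.tsv", sep="\t", index=False
    )
    back = [r for regions in result.back_projected.values() for r in regions]
    write_regions_bed(back, outdir / "conserved_backprojected.bed")
    drop_report(result.curation.dropped).to_csv(
        outdir / "drop_report.tsv", sep="\t", index=False
    )

    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"amycon_version={__version__}\n")
        fh.write(f"seed={'' if seed is None else seed}\n")
        fh.write(f"scorer_provenance={provenance}\n")
        fh.write(f"n_input_records={len(result.kept_records) + len(result.curation.dropped)}\n")
        fh.write(f"n_kept_records={len(result.kept_records)}\n")
        for key, value in config.to_dict().items():
            note = (
                f"  # published default {PUBLISHED_DEFAULTS[key]}"
                if key in PUBLISHED_DEFAULTS
                else "  # package default"
            )
            fh.write(f"{key}={value}{note}\n")

    if heatmap:
        from .plot import profile_heatmap

        profile_heatmap(result.profile, outdir / "heatmap.png")
    return outdir


def read_config_file(path: str | Path) -> tuple[AnalysisConfig, dict[str, str]]:
    """Parse a key=value config file (optionally with [analysis]/[family]).

    Returns the analysis config plus any raw [family] overrides for the
    synthetic generator.  A file with no section headers is treated as one
    [analysis] section.
    """
    text = Path(path).read_text()
    parser = configparser.ConfigParser()
    try:
        parser.read_string(text)
    except configparser.MissingSectionHeaderError:
        parser.read_string("[analysis]\n" + text)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    analysis: Mapping[str, str] = {}
    family: dict[str, str] = {}
    for section in parser.sections():
        if section == "analysis":
            analysis = dict(parser.items(section))
        elif section == "family":
            family = dict(parser.items(section))
        else:
            raise ConfigError(f"unknown config section [{section}]")
    return AnalysisConfig.from_mapping(analysis), family
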