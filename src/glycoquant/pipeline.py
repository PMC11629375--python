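"""End-to-end orchestration: sum spectra -> calibrate -> integrate ->
curate -> quantify -> profile, over an in-memory cohort or a directory of
spectrum files."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Analyte, AnalyteRole, LabelState
from .curation import (
    CurationReport,
    QCRule,
    Role,
    SampleMeta,
    analyte_consensus,
    merge_charges,
    read_metadata_tsv,
    spectral_curation,
)
from .extraction import (
    CalibrationModel,
    ExtractionConfig,
    ExtractionResult,
    calibration_points,
    extract_sample,
    fit_calibration_from_points,
)
from .panels import build_default_panel, quant_panels_from, read_analyte_tsv
from .profiling import relative_profile
from .quantitation import SpikeConfig, quantify_sample
from .spectra import Scan, read_scans, sum_spectra, write_table

logger = logging.getLogger("glycoquant")

__all__ = [
    "PipelineConfig",
    "SampleExtraction",
    "CohortResult",
    "process_sample",
    "run_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    qc_rule: QCRule = field(default_factory=QCRule)
    presence_cutoff: float = 0.80
    curation_percentile: float = 95.0
    include_ttp: bool = False
    consensus_groups: Optional[tuple[str, ...]] = None  # None -> all case groups

    def as_dict(self) -> dict:
        return {
            "extraction": vars(self.extraction),
            "spike": {
                "sil_mass_ng": self.spike.sil_mass_ng,
                "plasma_volume_ml": self.spike.plasma_volume_ml,
                "lloq_ng_ml": self.spike.lloq_ng_ml,
                "uloq_ng_ml": self.spike.uloq_ng_ml,
            },
            "qc_rule": self.qc_rule.as_dict(),
            "presence_cutoff": self.presence_cutoff,
            "curation_percentile": self.curation_percentile,
            "include_ttp": self.include_ttp,
            "consensus_groups": self.consensus_groups,
        }


@dataclass
class SampleExtraction:
    sample_id: str
    results: list[ExtractionResult]
    calibration: CalibrationModel


def process_sample(
    scans: Sequence[Scan],
    panel: Sequence[Analyte],
    config: Optional[PipelineConfig] = None,
    sample_id: str = "",
) -> SampleExtraction:
    """Sum per retention window, fit one calibration model from all SIL
    calibrant charge states, and integrate the full panel."""
    config = config or PipelineConfig()
    windows = sorted({a.rt_window for a in panel if a.role is not AnalyteRole.EXCLUDED})
    spectra = {w: sum_spectra(scans, w) for w in windows}

    points = []
    for window in windows:
        calibrants = [
            a
            for a in panel
            if a.rt_window == window
            and a.role in (AnalyteRole.CALIBRANT, AnalyteRole.BOTH)
        ]
        if calibrants:
            points.extend(
                calibration_points(spectra[window], calibrants, config.extraction)
            )
    calibration = fit_calibration_from_points(points)

    results: list[ExtractionResult] = []
    for window in windows:
        window_panel = [
            a
            for a in panel
            if a.rt_window == window and a.role is not AnalyteRole.EXCLUDED
        ]
        results.extend(
            extract_sample(
                spectra[window], window_panel, config.extraction, calibration
            )
        )
    results.sort(key=lambda r: (r.analyte_id, r.charge))
    logger.info(
        "sample %s: calibration=%s (%d points), %d extractions",
        sample_id, calibration.kind, len(calibration.calibrants_used), len(results),
    )
    return SampleExtraction(sample_id, results, calibration)


@dataclass
class CohortResult:
    extractions: dict[str, list[ExtractionResult]]
    calibration_kinds: dict[str, str]
    curation: CurationReport
    consensus: list[str]
    quants: pd.DataFrame
    profiles: pd.DataFrame
    traits: pd.DataFrame
    failed_samples: dict[str, str] = field(default_factory=dict)

    def extraction_frame(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.extractions):
            for r in self.extractions[sid]:
                rows.append(
                    {
                        "sample_id": sid,
                        "analyte_id": r.analyte_id,
                        "charge": r.charge,
                        "raw_area": r.raw_area,
                        "coverage": r.coverage,
                        "corrected_area": r.corrected_area,
                        "sn": r.sn,
                        "ppm_error": r.ppm_error,
                        "ipq": r.ipq,
                        "calibrated": r.calibrated,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(
    samples: Iterable[tuple[SampleMeta, Sequence[Scan]]],
    panel: Optional[Sequence[Analyte]] = None,
    config: Optional[PipelineConfig] = None,
) -> CohortResult:
    """Run the full pipeline over (metadata, scans) pairs.

    Per-sample processing failures are recorded and skipped so one corrupt
    sample cannot abort a cohort run.
    """
    config = config or PipelineConfig()
    if panel is None:
        panel = build_default_panel()

    metas: list[SampleMeta] = []
    extractions: dict[str, list[ExtractionResult]] = {}
    calibration_kinds: dict[str, str] = {}
    failed: dict[str, str] = {}
    for meta, scans in samples:
        metas.append(meta)
        try:
            extracted = process_sample(scans, panel, config, sample_id=meta.sample_id)
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.warning("sample %s failed: %s", meta.sample_id, exc)
            failed[meta.sample_id] = str(exc)
            continue
        extractions[meta.sample_id] = extracted.results
        calibration_kinds[meta.sample_id] = extracted.calibration.kind

    nat_glyco = sorted(
        a.id
        for a in panel
        if a.is_glyco
        and a.backbone.label_state is LabelState.NATURAL
        and a.id.startswith("IgG1")
    )
    sil_glyco = sorted(
        a.id for a in panel if a.is_glyco and a.backbone.label_state is LabelState.SIL
    )

    curation = spectral_curation(
        extractions, metas, nat_glyco, sil_glyco, config.curation_percentile
    )
    curation.qc_thresholds = config.qc_rule.as_dict()

    curated_cases = [
        sid
        for sid in curation.passed_ids
        if any(m.sample_id == sid and m.role is Role.CASE for m in metas)
    ]
    groups = config.consensus_groups
    if groups is None:
        # only groups that actually have curated case spectra can vote
        groups = tuple(
            sorted(
                {
                    m.group
                    for m in metas
                    if m.role is Role.CASE and m.group and m.sample_id in curated_cases
                }
            )
        )
    if groups and curated_cases:
        consensus = analyte_consensus(
            extractions,
            metas,
            groups,
            pass_rule=config.qc_rule,
            presence_cutoff=config.presence_cutoff,
            candidate_analytes=nat_glyco,
            curated_ids=curated_cases,
        )
    else:
        consensus = []

    panels = quant_panels_from(panel, consensus=consensus or nat_glyco,
                               include_ttp=config.include_ttp)

    quant_rows = []
    profile_rows = []
    trait_rows = []
    consensus_panel = [a for a in panel if a.id in set(consensus or nat_glyco)]
    igg3_panel = [
        a
        for a in panel
        if a.is_glyco
        and a.backbone.label_state is LabelState.NATURAL
        and a.id.startswith("IgG3")
    ]
    for sid in sorted(extractions):
        merged = merge_charges(extractions[sid])
        passed = curation.per_sample[sid].passed
        quant = quantify_sample(sid, merged, panels, config.spike, curation_passed=passed)
        quant_rows.append(quant.as_dict())
        if not passed:
            continue
        for subclass, sub_panel in (("IgG1", consensus_panel), ("IgG3", igg3_panel)):
            if not sub_panel:
                continue
            profile = relative_profile(merged, sub_panel, subclass=subclass)
            if profile is None:
                continue
            for glycoform, fraction in profile.rel_abundance.items():
                profile_rows.append(
                    {
                        "sample_id": sid,
                        "subclass": subclass,
                        "glycoform": glycoform,
                        "rel_abundance": fraction,
                    }
                )
            for trait, value in profile.traits.items():
                trait_rows.append(
                    {"sample_id": sid, "subclass": subclass, "trait": trait, "value": value}
                )

    return CohortResult(
        extractions=extractions,
        calibration_kinds=calibration_kinds,
        curation=curation,
        consensus=consensus,
        quants=pd.DataFrame(quant_rows),
        profiles=pd.DataFrame(profile_rows),
        traits=pd.DataFrame(trait_rows),
        failed_samples=failed,
    )


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    panel_path: Optional[str | Path] = None,
    metadata_path: Optional[str | Path] = None,
    config: Optional[PipelineConfig] = None,
) -> CohortResult:
    """File-based pipeline: read spectra + metadata (+ optional analyte
    table), run the cohort, and write all result tables into ``out_dir``."""
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    panel = read_analyte_tsv(panel_path) if panel_path else build_default_panel()
    metadata_path = Path(metadata_path) if metadata_path else input_dir / "metadata.tsv"
    if not Path(metadata_path).exists():
        raise FileNotFoundError(f"metadata table not found: {metadata_path}")
    metas = read_metadata_tsv(metadata_path)

    def sample_stream():
        for meta in metas:
            path = None
            for suffix in (".mzxml", ".tsv"):
                candidate = input_dir / f"{meta.sample_id}{suffix}"
                if candidate.exists():
                    path = candidate
                    break
            if path is None:
                logger.warning("no spectrum file for sample %s", meta.sample_id)
                continue
            try:
                scans = read_scans(path)
            except Exception as exc:  # noqa: BLE001
                logger.warning("sample %s unreadable: %s", meta.sample_id, exc)
                yield meta, []  # recorded as failed by run_cohort
                continue
            yield meta, scans

    result = run_cohort(sample_stream(), panel, config)

    write_table(result.extraction_frame(), out_dir / "extraction.tsv", "extraction")
    result.curation.write(out_dir / "curation.tsv", out_dir / "curation_summary.json")
    write_table(result.quants, out_dir / "quantitation.tsv", "quantitation")
    write_table(result.profiles, out_dir / "profiles.tsv", "profiles")
    write_table(result.traits, out_dir / "traits.tsv", "traits")
    pd.DataFrame(
        {"analyte_id": result.consensus}
    ).to_csv(out_dir / "consensus.tsv", sep="\t", index=False)
    (out_dir / "run_config.json").write_text(
        json.dumps(config.as_dict(), indent=2, default=str) + "\n"
    )
    return result
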