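"""QC-driven curation: negative-control-based spectral curation and the
analyte consensus list.

Spectral curation uses antibody-deficient negative-control samples to define
the assay background: per sample, the ratio of total natural signal over
total SIL-standard signal is computed, and the 95th percentile of that ratio
among the negative controls becomes a cutoff below which samples are
excluded.  The cutoff uses the conservative "higher" order-statistic
definition of the percentile, which guarantees that at most 5% of the
negative controls themselves exceed it for any continuous ratio
distribution.

The analyte consensus list keeps a glycopeptide only if it meets the QC pass
rule in at least 80% (configurable) of the curated spectra of every listed
biological group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import ExtractionResult
from .spectra import read_table, write_table

__all__ = [
    "Role",
    "SampleMeta",
    "SampleCuration",
    "CurationReport",
    "QCRule",
    "MergedResult",
    "merge_charges",
    "spectral_curation",
    "analyte_consensus",
    "read_metadata_tsv",
    "write_metadata_tsv",
]


class Role(str, Enum):
    CASE = "case"
    NEGATIVE_CONTROL = "negative_control"
    POOL_REPLICATE = "pool_replicate"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    role: Role
    group: str = ""
    batch: str = ""


@dataclass
class SampleCuration:
    nat_total: float
    sil_total: float
    ratio: float
    passed: bool
    reason: str = ""


@dataclass
class CurationReport:
    cutoff_ratio: float
    per_sample: dict[str, SampleCuration]
    qc_thresholds: dict = field(default_factory=dict)

    @property
    def passed_ids(self) -> list[str]:
        return sorted(s for s, c in self.per_sample.items() if c.passed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": sid,
                "nat_total": c.nat_total,
                "sil_total": c.sil_total,
                "ratio": c.ratio,
                "passed": c.passed,
                "reason": c.reason,
            }
            for sid, c in sorted(self.per_sample.items())
        ]
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
        write_table(self.to_frame(), tsv_path, "curation")
        if json_path is not None:
            n_pass = sum(c.passed for c in self.per_sample.values())
            summary = {
                "cutoff_ratio": self.cutoff_ratio,
                "n_samples": len(self.per_sample),
                "n_included": n_pass,
                "n_excluded": len(self.per_sample) - n_pass,
                "qc_thresholds": self.qc_thresholds,
            }
            Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


@dataclass(frozen=True)
class QCRule:
    """Per-analyte QC pass rule applied after charge-state merging."""

    min_sn: float = 9.0
    max_abs_ppm: float = 20.0
    max_ipq: float = 0.25

    def passes(self, merged: "MergedResult") -> bool:
        if not merged.corrected_area > 0:
            return False
        if merged.sn < self.min_sn or merged.ipq > self.max_ipq:
            return False
        if np.isnan(merged.ppm_error) or abs(merged.ppm_error) > self.max_abs_ppm:
            return False
        return True

    def as_dict(self) -> dict:
        return {"min_sn": self.min_sn, "max_abs_ppm": self.max_abs_ppm, "max_ipq": self.max_ipq}


@dataclass
class MergedResult:
    """Charge-state-merged metrics for one analyte in one sample: areas are
    summed; S/N is the best charge state; ppm error and IPQ are
    area-weighted means."""

    analyte_id: str
    corrected_area: float
    raw_area: float
    sn: float
    ppm_error: float
    ipq: float


def merge_charges(results: Sequence[ExtractionResult]) -> dict[str, MergedResult]:
    merged: dict[str, MergedResult] = {}
    for analyte_id in sorted({r.analyte_id for r in results}):
        group = [r for r in results if r.analyte_id == analyte_id]
        corrected = sum(r.corrected_area for r in group)
        raw = sum(r.raw_area for r in group)
        sn = max(r.sn for r in group)
        weights = np.array([r.corrected_area for r in group])
        if weights.sum() > 0:
            w = weights / weights.sum()
            ppm_values = np.array([r.ppm_error for r in group])
            valid = ~np.isnan(ppm_values)
            ppm = float(np.sum(w[valid] * ppm_values[valid]) / w[valid].sum()) if valid.any() else np.nan
            ipq = float(np.sum(w * np.array([r.ipq for r in group])))
        else:
            ppm, ipq = np.nan, 0.0
        merged[analyte_id] = MergedResult(analyte_id, corrected, raw, sn, ppm, ipq)
    return merged


def _metadata_map(meta: Sequence[SampleMeta] | Mapping[str, SampleMeta]) -> dict[str, SampleMeta]:
    if isinstance(meta, Mapping):
        return dict(meta)
    out: dict[str, SampleMeta] = {}
    for m in meta:
        if m.sample_id in out:
            raise ValueError(f"duplicate sample_id in metadata: {m.sample_id}")
        out[m.sample_id] = m
    return out


def spectral_curation(
    extractions: Mapping[str, Sequence[ExtractionResult]],
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    natural_panel: Sequence[str],
    sil_panel: Sequence[str],
    percentile: float = 95.0,
) -> CurationReport:
    """Flag samples whose natural/SIL total intensity ratio does not exceed
    the negative-control background cutoff.

    Negative controls are always marked failed for downstream quantitation;
    a sample with zero SIL signal fails with reason ``standard absent``.
    """
    meta_map = _metadata_map(meta)
    nat_set, sil_set = set(natural_panel), set(sil_panel)
    if not nat_set or not sil_set:
        raise ValueError("natural and SIL panels must be non-empty")
    negatives = [
        sid
        for sid in extractions
        if meta_map.get(sid) and meta_map[sid].role is Role.NEGATIVE_CONTROL
    ]
    if len(negatives) < 3:
        raise ValueError(
            f"spectral curation needs >= 3 negative controls, got {len(negatives)}"
        )

    per_sample: dict[str, SampleCuration] = {}
    for sid, results in extractions.items():
        nat = sum(r.corrected_area for r in results if r.analyte_id in nat_set)
        sil = sum(r.corrected_area for r in results if r.analyte_id in sil_set)
        if sil > 0:
            per_sample[sid] = SampleCuration(nat, sil, nat / sil, passed=False)
        else:
            per_sample[sid] = SampleCuration(
                nat, sil, np.nan, passed=False, reason="standard absent"
            )

    negative_ratios = [
        per_sample[sid].ratio for sid in negatives if np.isfinite(per_sample[sid].ratio)
    ]
    if len(negative_ratios) < 3:
        raise ValueError("fewer than 3 negative controls with usable SIL signal")
    cutoff = float(np.percentile(negative_ratios, percentile, method="higher"))

    for sid, curation in per_sample.items():
        if curation.reason:
            continue
        if meta_map.get(sid) and meta_map[sid].role is Role.NEGATIVE_CONTROL:
            curation.reason = "negative control"
            continue
        if curation.ratio > cutoff:
            curation.passed = True
        else:
            curation.reason = "below background cutoff"
    return CurationReport(cutoff_ratio=cutoff, per_sample=per_sample)


def analyte_consensus(
    extractions: Mapping[str, Sequence[ExtractionResult]],
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    groups: Sequence[str],
    pass_rule: Optional[QCRule] = None,
    presence_cutoff: float = 0.80,
    candidate_analytes: Optional[Sequence[str]] = None,
    curated_ids: Optional[Sequence[str]] = None,
    require_all_groups: bool = True,
) -> list[str]:
    """Consensus analyte list: an analyte is kept iff it passes the QC rule
    in at least ``presence_cutoff`` (inclusive) of the curated spectra of
    every listed group (or any group, if ``require_all_groups`` is False)."""
    if not groups:
        raise ValueError("no biological groups given")
    pass_rule = pass_rule or QCRule()
    meta_map = _metadata_map(meta)
    usable = set(curated_ids) if curated_ids is not None else set(extractions)

    merged_by_sample = {
        sid: merge_charges(results)
        for sid, results in extractions.items()
        if sid in usable
    }
    if candidate_analytes is None:
        candidates = sorted({a for m in merged_by_sample.values() for a in m})
    else:
        candidates = sorted(candidate_analytes)

    group_samples: dict[str, list[str]] = {}
    for g in groups:
        members = [
            sid
            for sid in merged_by_sample
            if meta_map.get(sid) and meta_map[sid].group == g
        ]
        if not members:
            raise ValueError(f"biological group {g!r} has no curated spectra")
        group_samples[g] = members

    consensus = []
    for analyte_id in candidates:
        fractions = []
        for g, members in group_samples.items():
            n_pass = sum(
                1
                for sid in members
                if analyte_id in merged_by_sample[sid]
                and pass_rule.passes(merged_by_sample[sid][analyte_id])
            )
            fractions.append(n_pass / len(members))
        ok = (
            all(f >= presence_cutoff - 1e-12 for f in fractions)
            if require_all_groups
            else any(f >= presence_cutoff - 1e-12 for f in fractions)
        )
        if ok:
            consensus.append(analyte_id)
    return consensus


def read_metadata_tsv(path: str | Path) -> list[SampleMeta]:
    df = read_table(path)
    required = {"sample_id", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata {path} must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                role=Role(row["role"]),
                group="" if pd.isna(row.get("group", "")) else str(row.get("group", "")),
                batch="" if pd.isna(row.get("batch", "")) else str(row.get("batch", "")),
            )
        )
    return out


def write_metadata_tsv(path: str | Path, meta: Sequence[SampleMeta]) -> None:
    df = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "role": m.role.value, "group": m.group, "batch": m.batch}
            for m in meta
        ]
    )
    write_table(df, path, "metadata")
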