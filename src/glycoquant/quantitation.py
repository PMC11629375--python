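"""Absolute IgG quantitation from natural/SIL intensity ratios.

A known mass of a stable-isotope-labeled IgG1 standard is spiked into every
sample eluate, so the concentration of the natural antigen-specific IgG1 in
the original plasma volume follows directly from the intensity ratio:

    conc [ng/mL] = (sum natural / sum SIL) * (spike mass [ng] / plasma volume [mL])

With the default spike of 2 ng into 0.02 mL of plasma, a unit ratio maps to
exactly 100 ng/mL.  The same formula is evaluated on three independent
analyte classes — the summed glycopeptides, the proteotypic GPS peptide and
(optionally) the TTP peptide — and composited as their median for robustness
against single-analyte interference.  IgG3 can be quantified with the same
machinery against the IgG1 SIL standard, with the caveat of a cross-subclass
standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import MergedResult

__all__ = [
    "SpikeConfig",
    "SampleQuant",
    "QuantPanels",
    "conc_from_glycopeptides",
    "conc_from_peptide",
    "conc_igg3",
    "composite_concentration",
    "quantify_sample",
]


@dataclass(frozen=True)
class SpikeConfig:
    """SIL spike amount and captured plasma volume, plus reporting limits."""

    sil_mass_ng: float = 2.0
    plasma_volume_ml: float = 0.02
    lloq_ng_ml: float = 100.0
    uloq_ng_ml: float = 10000.0

    def __post_init__(self) -> None:
        if self.sil_mass_ng <= 0 or self.plasma_volume_ml <= 0:
            raise ValueError("spike mass and plasma volume must be positive")

    @property
    def scale(self) -> float:
        """ng/mL per unit natural/SIL ratio."""
        return self.sil_mass_ng / self.plasma_volume_ml


def _ratio_concentration(nat: float, sil: float, spike: SpikeConfig) -> float:
    if sil <= 0:
        return math.nan
    if nat < 0:
        raise ValueError("negative natural intensity")
    return nat / sil * spike.scale


def conc_from_glycopeptides(nat_sum: float, sil_sum: float, spike: SpikeConfig) -> float:
    """Concentration from charge- and coverage-corrected glycopeptide sums.

    Returns NaN when the SIL sum is non-positive (standard failure); the
    caller flags the sample.
    """
    return _ratio_concentration(nat_sum, sil_sum, spike)


def conc_from_peptide(nat_intensity: float, sil_intensity: float, spike: SpikeConfig) -> float:
    """Concentration from one natural/SIL peptide pair (corrected areas of
    the uncalibrated [M+2H]2+ extraction)."""
    return _ratio_concentration(nat_intensity, sil_intensity, spike)


def conc_igg3(nat_igg3_sum: float, sil_igg1_sum: float, spike: SpikeConfig) -> float:
    """IgG3 concentration against the IgG1 SIL standard (cross-subclass
    standard: assumes equal response factors, so interpret with care)."""
    return _ratio_concentration(nat_igg3_sum, sil_igg1_sum, spike)


def composite_concentration(per_class_concs: Sequence[float]) -> float:
    """Median of the available per-analyte-class concentrations."""
    values = [c for c in per_class_concs if c is not None and np.isfinite(c)]
    if not values:
        return math.nan
    return float(np.median(values))


@dataclass(frozen=True)
class QuantPanels:
    """Analyte ids entering each quantitation class."""

    nat_glyco: tuple[str, ...]
    sil_glyco: tuple[str, ...]
    gps_pair: tuple[str, str]          # (natural id, SIL id)
    ttp_pair: Optional[tuple[str, str]] = None
    include_ttp: bool = False
    igg3_glyco: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.nat_glyco or not self.sil_glyco:
            raise ValueError("glycopeptide panels must be non-empty")


@dataclass
class SampleQuant:
    sample_id: str
    conc_glyco: float
    conc_gps: float
    conc_ttp: float
    conc_composite: float
    conc_igg3: float
    below_lloq: bool
    above_uloq: bool
    curation_passed: bool
    standard_absent: bool

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "conc_glyco": self.conc_glyco,
            "conc_gps": self.conc_gps,
            "conc_ttp": self.conc_ttp,
            "conc_composite": self.conc_composite,
            "conc_igg3": self.conc_igg3,
            "below_lloq": self.below_lloq,
            "above_uloq": self.above_uloq,
            "curation_passed": self.curation_passed,
            "standard_absent": self.standard_absent,
        }


def quantify_sample(
    sample_id: str,
    merged: Mapping[str, MergedResult],
    panels: QuantPanels,
    spike: SpikeConfig,
    curation_passed: bool = True,
) -> SampleQuant:
    """Per-sample concentrations from charge-merged corrected areas.

    The composite is the median of the glycopeptide- and GPS-derived values
    (TTP included only when explicitly enabled).  LLOQ/ULOQ are reporting
    flags, not truncation.
    """

    def area_sum(ids: Sequence[str]) -> float:
        return float(sum(merged[a].corrected_area for a in ids if a in merged))

    sil_sum = area_sum(panels.sil_glyco)
    nat_sum = area_sum(panels.nat_glyco)
    glyco = conc_from_glycopeptides(nat_sum, sil_sum, spike)

    gps_nat, gps_sil = panels.gps_pair
    gps = conc_from_peptide(
        merged[gps_nat].corrected_area if gps_nat in merged else 0.0,
        merged[gps_sil].corrected_area if gps_sil in merged else 0.0,
        spike,
    )

    ttp = math.nan
    if panels.ttp_pair is not None:
        ttp_nat, ttp_sil = panels.ttp_pair
        ttp = conc_from_peptide(
            merged[ttp_nat].corrected_area if ttp_nat in merged else 0.0,
            merged[ttp_sil].corrected_area if ttp_sil in merged else 0.0,
            spike,
        )

    classes = [glyco, gps] + ([ttp] if panels.include_ttp else [])
    composite = composite_concentration(classes)

    igg3 = math.nan
    if panels.igg3_glyco:
        igg3 = conc_igg3(area_sum(panels.igg3_glyco), sil_sum, spike)

    return SampleQuant(
        sample_id=sample_id,
        conc_glyco=glyco,
        conc_gps=gps,
        conc_ttp=ttp,
        conc_composite=composite,
        conc_igg3=igg3,
        below_lloq=bool(np.isfinite(composite) and composite < spike.lloq_ng_ml),
        above_uloq=bool(np.isfinite(composite) and composite > spike.uloq_ng_ml),
        curation_passed=curation_passed,
        standard_absent=not sil_sum > 0,
    )
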