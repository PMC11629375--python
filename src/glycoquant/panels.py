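"""Default analyte panels and the analyte definition table.

The IgG1 Fc glycopeptide backbone is EEQYNSTYR and the IgG3 backbone
EEQYNSTFR (both configurable); the proteotypic quantitation peptides are
GPSVFPLAPSSK (GPS) and TTPPVLDSDGSFFLYSK (TTP).  The SIL standard
contributes its three most abundant glycoforms (G0, G0F, G1F) plus labeled
GPS/TTP.  The default natural IgG1 glycoform panel is a ten-form stand-in
covering the common biantennary forms; override it with an analyte table to
match a specific assay.

Retention-time windows are instrument facts, not constants of the method;
the defaults here simply match the synthetic data generator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .chem import (
    Analyte,
    AnalyteRole,
    GlycanComposition,
    LabelState,
    PeptideBackbone,
)
from .quantitation import QuantPanels
from .spectra import read_table, write_table

__all__ = [
    "IGG1_BACKBONE",
    "IGG3_BACKBONE",
    "GPS_SEQUENCE",
    "TTP_SEQUENCE",
    "DEFAULT_IGG1_GLYCOFORMS",
    "DEFAULT_IGG3_GLYCOFORMS",
    "SIL_GLYCOFORMS",
    "build_default_panel",
    "quant_panels_from",
    "read_analyte_tsv",
    "write_analyte_tsv",
]

IGG1_BACKBONE = "EEQYNSTYR"
IGG3_BACKBONE = "EEQYNSTFR"
GPS_SEQUENCE = "GPSVFPLAPSSK"
TTP_SEQUENCE = "TTPPVLDSDGSFFLYSK"

#: Default natural IgG1 glycoform panel with typical plasma-IgG1 mean
#: fractional abundances (used as generator defaults; they sum to 1).
DEFAULT_IGG1_GLYCOFORMS: dict[str, float] = {
    "G0": 0.05,
    "G0F": 0.30,
    "G0FN": 0.04,
    "G1": 0.04,
    "G1F": 0.30,
    "G1FN": 0.03,
    "G1FS": 0.04,
    "G2": 0.02,
    "G2F": 0.15,
    "G2FS": 0.03,
}

#: IgG3 panel restricted to the six glycoforms quantified cross-subclass.
DEFAULT_IGG3_GLYCOFORMS: dict[str, float] = {
    "G0F": 0.35,
    "G1F": 0.30,
    "G1FN": 0.05,
    "G1FS": 0.08,
    "G2F": 0.15,
    "G2FS": 0.07,
}

#: The three well-quantifiable glycoforms of the CHO-produced SIL standard,
#: with its characteristically narrow glycoform distribution.
SIL_GLYCOFORMS: dict[str, float] = {"G0": 0.25, "G0F": 0.55, "G1F": 0.20}

IGG1_GLYCO_RT = (48.0, 62.0)
IGG3_GLYCO_RT = (70.0, 84.0)
GPS_RT = (120.0, 134.0)
TTP_RT = (150.0, 164.0)

GLYCO_CHARGES = (2, 3)
PEPTIDE_CHARGES = (2,)


def build_default_panel(
    include_igg3: bool = False,
    igg1_backbone: str = IGG1_BACKBONE,
    igg3_backbone: str = IGG3_BACKBONE,
) -> list[Analyte]:
    """Construct the default analyte panel (natural + SIL species)."""
    panel: list[Analyte] = []
    nat_bb = PeptideBackbone(igg1_backbone, LabelState.NATURAL, glyco_site=4)
    sil_bb = PeptideBackbone(igg1_backbone, LabelState.SIL, glyco_site=4)
    for name in DEFAULT_IGG1_GLYCOFORMS:
        panel.append(
            Analyte(
                id=f"IgG1-{name}",
                backbone=nat_bb,
                glycan=GlycanComposition.from_name(name),
                charges=GLYCO_CHARGES,
                rt_window=IGG1_GLYCO_RT,
                role=AnalyteRole.QUANTIFIER,
            )
        )
    for name in SIL_GLYCOFORMS:
        panel.append(
            Analyte(
                id=f"IgG1-{name}-SIL",
                backbone=sil_bb,
                glycan=GlycanComposition.from_name(name),
                charges=GLYCO_CHARGES,
                rt_window=IGG1_GLYCO_RT,
                role=AnalyteRole.BOTH,
            )
        )
    if include_igg3:
        igg3_bb = PeptideBackbone(igg3_backbone, LabelState.NATURAL, glyco_site=4)
        for name in DEFAULT_IGG3_GLYCOFORMS:
            panel.append(
                Analyte(
                    id=f"IgG3-{name}",
                    backbone=igg3_bb,
                    glycan=GlycanComposition.from_name(name),
                    charges=GLYCO_CHARGES,
                    rt_window=IGG3_GLYCO_RT,
                    role=AnalyteRole.QUANTIFIER,
                )
            )
    for seq, label, rt in (
        (GPS_SEQUENCE, "GPS", GPS_RT),
        (TTP_SEQUENCE, "TTP", TTP_RT),
    ):
        panel.append(
            Analyte(
                id=label,
                backbone=PeptideBackbone(seq, LabelState.NATURAL),
                charges=PEPTIDE_CHARGES,
                rt_window=rt,
                role=AnalyteRole.QUANTIFIER,
            )
        )
        panel.append(
            Analyte(
                id=f"{label}-SIL",
                backbone=PeptideBackbone(seq, LabelState.SIL),
                charges=PEPTIDE_CHARGES,
                rt_window=rt,
                role=AnalyteRole.QUANTIFIER,
            )
        )
    return panel


def quant_panels_from(
    panel: Sequence[Analyte],
    consensus: Optional[Sequence[str]] = None,
    include_ttp: bool = False,
) -> QuantPanels:
    """Derive the quantitation panels from an analyte panel, optionally
    restricting the natural glycopeptides to a consensus list."""
    nat = [
        a.id
        for a in panel
        if a.is_glyco
        and a.backbone.label_state is LabelState.NATURAL
        and a.id.startswith("IgG1")
    ]
    if consensus is not None:
        nat = [a for a in nat if a in set(consensus)]
    sil = [
        a.id
        for a in panel
        if a.is_glyco and a.backbone.label_state is LabelState.SIL
    ]
    igg3 = tuple(
        a.id
        for a in panel
        if a.is_glyco
        and a.backbone.label_state is LabelState.NATURAL
        and a.id.startswith("IgG3")
    )
    ids = {a.id for a in panel}
    ttp_pair = ("TTP", "TTP-SIL") if {"TTP", "TTP-SIL"} <= ids else None
    return QuantPanels(
        nat_glyco=tuple(sorted(nat)),
        sil_glyco=tuple(sorted(sil)),
        gps_pair=("GPS", "GPS-SIL"),
        ttp_pair=ttp_pair,
        include_ttp=include_ttp,
        igg3_glyco=igg3,
    )


def write_analyte_tsv(path: str | Path, panel: Sequence[Analyte]) -> None:
    rows = []
    for a in panel:
        rows.append(
            {
                "id": a.id,
                "sequence": a.backbone.sequence,
                "label": a.backbone.label_state.value,
                "glycan": a.glycan.short_name if a.glycan else "",
                "charges": ",".join(str(z) for z in a.charges),
                "rt_start_s": a.rt_window[0],
                "rt_end_s": a.rt_window[1],
                "role": a.role.value,
            }
        )
    write_table(pd.DataFrame(rows), path, "analytes")


def read_analyte_tsv(path: str | Path) -> list[Analyte]:
    df = read_table(path)
    required = {"id", "sequence", "label", "glycan", "charges", "rt_start_s", "rt_end_s", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"analyte table {path} missing columns: {sorted(missing)}")
    panel = []
    for _, row in df.iterrows():
        glycan = row["glycan"]
        glycan_str = "" if pd.isna(glycan) else str(glycan).strip()
        panel.append(
            Analyte(
                id=str(row["id"]),
                backbone=PeptideBackbone(str(row["sequence"]), LabelState(row["label"])),
                glycan=GlycanComposition.from_name(glycan_str) if glycan_str else None,
                charges=tuple(int(z) for z in str(row["charges"]).split(",")),
                rt_window=(float(row["rt_start_s"]), float(row["rt_end_s"])),
                role=AnalyteRole(row["role"]),
            )
        )
    return panel
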