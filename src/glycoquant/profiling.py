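"""Relative glycoform abundances and derived Fc glycosylation traits.

Relative abundances are corrected areas normalized over the consensus panel
of natural glycopeptides of one IgG subclass; SIL standard analytes never
enter the natural profile.  Traits follow the antenna-normalized convention
for biantennary IgG Fc glycans:

* fucosylation — summed abundance of core-fucosylated forms,
* bisection   — summed abundance of forms with a bisecting HexNAc,
* galactosylation — galactoses per antenna (0, 0.5 or 1 per glycoform),
* sialylation — sialic acids per antenna.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .chem import Analyte, GlycanComposition, LabelState
from .curation import MergedResult

__all__ = ["GlycoProfile", "relative_profile", "derived_traits"]

TRAIT_NAMES = ("fucosylation", "galactosylation", "sialylation", "bisection")


@dataclass
class GlycoProfile:
    subclass: str
    rel_abundance: dict[str, float]
    traits: dict[str, float] = field(default_factory=dict)


def relative_profile(
    merged: Mapping[str, MergedResult],
    panel: Sequence[Analyte],
    subclass: str = "IgG1",
) -> Optional[GlycoProfile]:
    """Normalized glycoform profile of one sample over a consensus panel.

    ``panel`` lists the natural glycopeptide analytes of the subclass (after
    charge merging).  Returns None when the panel total is zero (profile
    undefined; caller flags the sample).
    """
    if not panel:
        raise ValueError("empty consensus panel")
    natural = [
        a for a in panel if a.is_glyco and a.backbone.label_state is LabelState.NATURAL
    ]
    if not natural:
        raise ValueError("panel contains no natural glycopeptides")
    areas = {
        a.glycan.short_name: (
            merged[a.id].corrected_area if a.id in merged else 0.0
        )
        for a in natural
    }
    total = sum(areas.values())
    if not total > 0:
        return None
    rel = {name: area / total for name, area in sorted(areas.items())}
    return GlycoProfile(subclass=subclass, rel_abundance=rel, traits=derived_traits(rel))


def derived_traits(profile: Mapping[str, float]) -> dict[str, float]:
    """Antenna-normalized glycosylation traits from a glycoform profile.

    Unparseable glycoform names raise a ValueError naming the glycoform.
    """
    fuc = gal = sia = bis = 0.0
    for name, abundance in profile.items():
        try:
            comp = GlycanComposition.from_name(name)
        except ValueError as exc:
            raise ValueError(f"cannot derive traits for glycoform {name!r}") from exc
        if comp.fuc >= 1:
            fuc += abundance
        if comp.hexnac >= 5:
            bis += abundance
        gal += np.clip(comp.hex - 3, 0, 2) / 2.0 * abundance
        sia += comp.neuac / 2.0 * abundance
    return {
        "fucosylation": fuc,
        "galactosylation": gal,
        "sialylation": sia,
        "bisection": bis,
    }
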