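"""Chemistry core: elemental compositions, (glyco)peptide masses, SIL label
shifts, charge-state m/z and aggregated isotopologue patterns.

The quantitation method rests on a spiked stable-isotope-labeled (SIL) IgG1
standard carrying 13C/15N at every lysine and arginine.  A tryptic peptide
therefore gains exactly one labeled residue (its C-terminal K or R), shifting
the whole isotopologue cluster by a nominal 8 (Lys) or 10 (Arg) neutrons while
leaving its chemistry otherwise identical — the premise that natural and SIL
isotopologues ionize equally and can be ratioed.

Isotopologue patterns are aggregated by neutron-count offset above the
monoisotopic peak (not isotope fine structure), matching how narrow m/z
integration windows see a time-of-flight isotope cluster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np

from .constants import (
    ISOTOPE_OFFSETS,
    ISOTOPES,
    MONOSACCHARIDE_FORMULAS,
    PROTON_MASS,
    RESIDUE_FORMULAS,
    SIL_LABEL_ATOMS,
    WATER_FORMULA,
)

__all__ = [
    "ElementalComposition",
    "GlycanComposition",
    "LabelState",
    "PeptideBackbone",
    "Analyte",
    "AnalyteRole",
    "IsotopologuePattern",
    "PatternEntry",
    "peptide_composition",
    "glycan_composition_mass",
    "analyte_mz",
    "isotopologue_pattern",
    "sil_mass_shift",
    "mass_to_mz",
]

# relative tail mass below which convolution products are truncated; chosen
# so aggregate truncation error stays far below the 1e-9 total-variation
# agreement required against exhaustive enumeration
_TRIM_TAIL = 1e-14


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> count map, including the C13/N15 label pseudo-elements."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for element, count in self.counts.items():
            if element not in ISOTOPES:
                raise ValueError(f"unknown element: {element!r}")
            if int(count) != count or count < 0:
                raise ValueError(f"negative or non-integer count for {element}: {count}")
            if count > 0:
                clean[element] = int(count)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def monoisotopic_mass(self) -> float:
        """Mass with every atom as its lightest isotope (pseudo-elements are
        single-isotope, so labeled atoms contribute their heavy mass here)."""
        return sum(ISOTOPES[el][0][0] * n for el, n in self.counts.items())

    def key(self) -> tuple:
        return tuple(sorted(self.counts.items()))


class LabelState(str, Enum):
    NATURAL = "natural"
    SIL = "SIL"


class AnalyteRole(str, Enum):
    QUANTIFIER = "quantifier"
    CALIBRANT = "calibrant"
    BOTH = "both"
    EXCLUDED = "excluded"


_GLYCAN_NAME_RE = re.compile(r"^G([0-4])([FNS]*)$")


@dataclass(frozen=True)
class GlycanComposition:
    """N-glycan monosaccharide composition (Hex / HexNAc / dHex / NeuAc).

    Short names follow the IgG convention: the digit after ``G`` counts
    galactoses on the biantennary core (Hex = 3 + digit), ``F`` core fucose,
    ``N`` a bisecting HexNAc (HexNAc = 4 + 1) and ``S`` a sialic acid.
    """

    hex: int
    hexnac: int
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative monosaccharide count: {name}")

    @classmethod
    def from_name(cls, name: str) -> "GlycanComposition":
        match = _GLYCAN_NAME_RE.match(name.strip())
        if not match:
            raise ValueError(f"unsupported glycan short name: {name!r}")
        gal = int(match.group(1))
        letters = match.group(2)
        return cls(
            hex=3 + gal,
            hexnac=4 + letters.count("N"),
            fuc=letters.count("F"),
            neuac=letters.count("S"),
        )

    @property
    def short_name(self) -> str:
        gal = self.hex - 3
        bisect = self.hexnac - 4
        if not (0 <= gal <= 4 and 0 <= bisect):
            raise ValueError(f"composition {self} has no biantennary short name")
        return f"G{gal}" + "F" * self.fuc + "N" * bisect + "S" * self.neuac

    def elemental(self) -> ElementalComposition:
        counts: dict[str, int] = {}
        for sugar, number in (
            ("hex", self.hex),
            ("hexnac", self.hexnac),
            ("fuc", self.fuc),
            ("neuac", self.neuac),
        ):
            for element, per_residue in MONOSACCHARIDE_FORMULAS[sugar].items():
                counts[element] = counts.get(element, 0) + per_residue * number
        return ElementalComposition(counts)

    @property
    def mass(self) -> float:
        return self.elemental().monoisotopic_mass


def glycan_composition_mass(glycan: GlycanComposition) -> float:
    """Monoisotopic residue mass of a glycan composition in Da."""
    return glycan.mass


@dataclass(frozen=True)
class PeptideBackbone:
    """Tryptic peptide sequence plus label state.

    ``glyco_site`` is the 0-based position of the Asn of the N-glycosylation
    sequon when the peptide is a glycopeptide backbone; informational only.
    """

    sequence: str
    label_state: LabelState = LabelState.NATURAL
    glyco_site: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue: {ch!r}")
        if self.label_state is LabelState.SIL and self.sequence[-1] not in SIL_LABEL_ATOMS:
            raise ValueError(
                "SIL label requires a tryptic C-terminal K or R, got "
                f"{self.sequence[-1]!r}"
            )


def sil_mass_shift(residue: str) -> float:
    """Exact mass shift (Da) of a 13C6,15N2-Lys (8.0142) or 13C6,15N4-Arg
    (10.0083) relative to the natural residue."""
    if residue not in SIL_LABEL_ATOMS:
        raise ValueError(f"residue {residue!r} carries no SIL label (K or R only)")
    n_c, n_n = SIL_LABEL_ATOMS[residue]
    d_c = ISOTOPES["C13"][0][0] - ISOTOPES["C"][0][0]
    d_n = ISOTOPES["N15"][0][0] - ISOTOPES["N"][0][0]
    return n_c * d_c + n_n * d_n


def peptide_composition(backbone: PeptideBackbone) -> ElementalComposition:
    """Elemental composition of a peptide (residues + water), with the
    C-terminal K/R atoms moved to C13/N15 for the SIL state."""
    counts: dict[str, int] = dict(WATER_FORMULA)
    for residue in backbone.sequence:
        for element, per_residue in RESIDUE_FORMULAS[residue].items():
            counts[element] = counts.get(element, 0) + per_residue
    if backbone.label_state is LabelState.SIL:
        n_c, n_n = SIL_LABEL_ATOMS[backbone.sequence[-1]]
        counts["C"] -= n_c
        counts["N"] -= n_n
        counts["C13"] = counts.get("C13", 0) + n_c
        counts["N15"] = counts.get("N15", 0) + n_n
    return ElementalComposition(counts)


@dataclass(frozen=True)
class PatternEntry:
    offset: int           # neutrons above the monoisotopic peak
    exact_mass: float     # abundance-weighted mass of the aggregated peak, Da
    rel_abundance: float  # fraction of the *untruncated* pattern


@dataclass(frozen=True)
class IsotopologuePattern:
    """Aggregated isotopologue distribution, possibly truncated to the most
    abundant subset covering at least a requested total fraction."""

    entries: tuple[PatternEntry, ...]

    def __post_init__(self) -> None:
        offsets = [e.offset for e in self.entries]
        if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
            raise ValueError("pattern offsets must be strictly increasing")
        if any(e.rel_abundance < 0 for e in self.entries):
            raise ValueError("negative isotopologue abundance")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.entries], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([e.exact_mass for e in self.entries])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([e.rel_abundance for e in self.entries])

    @property
    def coverage(self) -> float:
        """Summed theoretical fraction of the retained isotopologues."""
        return float(self.fractions.sum())

    def mz(self, charge: int) -> np.ndarray:
        return (self.masses + charge * PROTON_MASS) / charge


def _trim(p: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tail = np.cumsum(p[::-1])[::-1]
    keep = int(np.searchsorted(-tail, -_TRIM_TAIL * p.sum()))
    keep = max(keep, 1)
    return p[:keep], m[:keep]


def _combine(pa, ma, pb, mb):
    """Convolve two (abundance, mean-extra-mass) offset distributions."""
    pc = np.convolve(pa, pb)
    num = np.convolve(pa * ma, pb) + np.convolve(pa, pb * mb)
    mc = num / np.where(pc > 0, pc, 1.0)
    return _trim(pc, mc)


def _element_power(element: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = ISOTOPE_OFFSETS[element]
    base_mass = ISOTOPES[element][0][0]
    size = max(offsets) + 1
    p1 = np.zeros(size)
    m1 = np.zeros(size)
    for (mass, abundance), offset in zip(ISOTOPES[element], offsets):
        p1[offset] += abundance
        m1[offset] = mass - base_mass
    # binary exponentiation of the single-atom distribution
    result_p, result_m = np.array([1.0]), np.array([0.0])
    base_p, base_m = p1, m1
    while n:
        if n & 1:
            result_p, result_m = _combine(result_p, result_m, base_p, base_m)
        n >>= 1
        if n:
            base_p, base_m = _combine(base_p, base_m, base_p, base_m)
    return result_p, result_m


_PATTERN_CACHE: dict[tuple, IsotopologuePattern] = {}


def isotopologue_pattern(
    comp: ElementalComposition, min_total_fraction: float = 1.0
) -> IsotopologuePattern:
    """Aggregated-by-neutron-count isotopologue pattern of a composition.

    Returns the most-abundant-first prefix of the full distribution whose
    theoretical fractions sum to at least ``min_total_fraction``, re-ordered
    by offset.  ``exact_mass`` per offset is the abundance-weighted mean mass
    of that offset's underlying fine structure.
    """
    if not 0 < min_total_fraction <= 1:
        raise ValueError("min_total_fraction must be in (0, 1]")
    if comp.total_atoms == 0:
        raise ValueError("empty elemental composition")
    key = (comp.key(), round(min_total_fraction, 12))
    cached = _PATTERN_CACHE.get(key)
    if cached is not None:
        return cached

    p, m = np.array([1.0]), np.array([0.0])
    for element, count in sorted(comp.counts.items()):
        ep, em = _element_power(element, count)
        p, m = _combine(p, m, ep, em)

    mono = comp.monoisotopic_mass
    order = np.argsort(-p, kind="stable")
    cum = np.cumsum(p[order])
    target = min(min_total_fraction, float(p.sum()))
    n_keep = int(np.searchsorted(cum, target - 1e-15)) + 1
    selected = np.sort(order[:n_keep])
    entries = tuple(
        PatternEntry(int(k), mono + float(m[k]), float(p[k])) for k in selected
    )
    pattern = IsotopologuePattern(entries)
    _PATTERN_CACHE[key] = pattern
    return pattern


def mass_to_mz(mass: float, charge: int) -> float:
    if charge <= 0:
        raise ValueError(f"charge must be positive, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class Analyte:
    """A targeted (glyco)peptide species at one or more charge states."""

    id: str
    backbone: PeptideBackbone
    glycan: Optional[GlycanComposition] = None
    charges: tuple[int, ...] = (2, 3)
    rt_window: tuple[float, float] = (0.0, 0.0)
    role: AnalyteRole = AnalyteRole.QUANTIFIER

    def __post_init__(self) -> None:
        if not self.charges:
            raise ValueError("analyte needs at least one charge state")
        if any(z < 1 for z in self.charges):
            raise ValueError("charge states must be >= 1")

    @property
    def is_glyco(self) -> bool:
        return self.glycan is not None

    def composition(self) -> ElementalComposition:
        comp = peptide_composition(self.backbone)
        if self.glycan is not None:
            comp = comp + self.glycan.elemental()
        return comp

    @property
    def monoisotopic_mass(self) -> float:
        return self.composition().monoisotopic_mass

    def mz(self, charge: int) -> float:
        if charge not in self.charges:
            raise ValueError(f"charge {charge} not configured for analyte {self.id}")
        return mass_to_mz(self.monoisotopic_mass, charge)

    def pattern(self, min_total_fraction: float) -> IsotopologuePattern:
        return isotopologue_pattern(self.composition(), min_total_fraction)


def analyte_mz(analyte: Analyte, charge: int) -> float:
    """m/z of the first (monoisotopic) isotopologue at a charge state."""
    return analyte.mz(charge)
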