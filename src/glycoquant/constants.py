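"""Physical constants and reference tables for peptide/glycan mass math.

Isotope masses and abundances are the IUPAC/CODATA standard values embedded
here as documented constants.  ``C13`` and ``N15`` are pseudo-elements used
for stable-isotope-labeled residues: each behaves as an isotopically pure
heavy atom (one isotope, 100% abundance).
"""

from __future__ import annotations

#: Mass of a proton in Da, used for all m/z computations.
PROTON_MASS = 1.007276

#: Per-element isotope tables: ``symbol -> [(exact mass Da, abundance), ...]``
#: sorted so the first entry is the lightest (monoisotopic) isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.003354835, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
    # isotopically pure pseudo-elements for SIL-labeled Lys/Arg atoms
    "C13": [(13.003354835, 1.0)],
    "N15": [(15.0001088984, 1.0)],
}

#: Neutron-count offset of each isotope relative to the lightest isotope of
#: the same element (parallel to :data:`ISOTOPES`).
ISOTOPE_OFFSETS: dict[str, list[int]] = {
    element: [int(round(mass - isotopes[0][0])) for mass, _ in isotopes]
    for element, isotopes in ISOTOPES.items()
}

#: Monoisotopic elemental formulas of the 20 canonical amino-acid residues
#: (residue = amino acid minus water, as found inside a peptide chain).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Water, added once per peptide (termini).
WATER_FORMULA: dict[str, int] = {"H": 2, "O": 1}

#: Monosaccharide *residue* formulas (condensed into the glycan chain, i.e.
#: the free sugar minus one water), so glycan attachment needs no further
#: water bookkeeping.
MONOSACCHARIDE_FORMULAS: dict[str, dict[str, int]] = {
    "hex": {"C": 6, "H": 10, "O": 5},       # hexose, 162.0528 Da
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},  # N-acetylhexosamine, 203.0794 Da
    "fuc": {"C": 6, "H": 10, "O": 4},       # deoxyhexose (fucose), 146.0579 Da
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},  # N-acetylneuraminic acid, 291.0954 Da
}

#: Number of carbons / nitrogens swapped to heavy pseudo-elements in a
#: stable-isotope-labeled (13C6,15N2) lysine or (13C6,15N4) arginine.
SIL_LABEL_ATOMS: dict[str, tuple[int, int]] = {"K": (6, 2), "R": (6, 4)}
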