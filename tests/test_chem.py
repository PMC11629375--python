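"""Chemistry core: masses, label shifts, m/z and isotopologue patterns.

The isotopologue pattern implementation (pairwise convolution with binary
exponentiation) is checked against an independent exhaustive enumeration
oracle over all per-element isotope count vectors.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoquant.chem import (
    Analyte,
    ElementalComposition,
    GlycanComposition,
    LabelState,
    PeptideBackbone,
    analyte_mz,
    glycan_composition_mass,
    isotopologue_pattern,
    peptide_composition,
    sil_mass_shift,
)
from glycoquant.constants import ISOTOPES


def test_peptide_monoisotopic_mass_matches_residue_table():
    comp = peptide_composition(PeptideBackbone("EEQYNSTYR"))
    assert comp.monoisotopic_mass == pytest.approx(1188.5047, abs=5e-4)


def test_sil_composition_shifts_by_nominal_neutrons():
    nat = peptide_composition(PeptideBackbone("GPSVFPLAPSSK"))
    sil = peptide_composition(PeptideBackbone("GPSVFPLAPSSK", LabelState.SIL))
    delta = sil.monoisotopic_mass - nat.monoisotopic_mass
    assert round(delta) == 8
    assert delta == pytest.approx(8.0142, abs=5e-4)
    # atom bookkeeping: 6 C and 2 N moved to the heavy pseudo-elements
    assert sil.counts["C13"] == 6 and sil.counts["N15"] == 2
    assert nat.counts["C"] - sil.counts["C"] == 6


@pytest.mark.parametrize(
    "residue,expected,nominal",
    [("K", 8.0142, 8), ("R", 10.0083, 10)],
)
def test_sil_mass_shift_values(residue, expected, nominal):
    shift = sil_mass_shift(residue)
    assert shift == pytest.approx(expected, abs=5e-5)
    assert round(shift) == nominal


def test_sil_mass_shift_rejects_unlabeled_residue():
    with pytest.raises(ValueError):
        sil_mass_shift("G")


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        PeptideBackbone("")


def test_unknown_residue_named_in_error():
    with pytest.raises(ValueError, match="B"):
        PeptideBackbone("EEQBR")


def test_sil_requires_tryptic_terminus():
    with pytest.raises(ValueError):
        PeptideBackbone("EEQYG", LabelState.SIL)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("G0F", 1444.5339),
        ("G0", 1298.4760),   # 3 Hex + 4 HexNAc
        ("G2FS", 2059.7349),  # G0F + 2 Hex + NeuAc
    ],
)
def test_glycan_masses(name, expected):
    assert glycan_composition_mass(GlycanComposition.from_name(name)) == pytest.approx(
        expected, abs=2e-3
    )


def test_single_hexose_increment():
    g1f = glycan_composition_mass(GlycanComposition.from_name("G1F"))
    g0f = glycan_composition_mass(GlycanComposition.from_name("G0F"))
    assert g1f - g0f == pytest.approx(162.0528, abs=1e-4)


def test_empty_glycan_mass_is_zero():
    assert glycan_composition_mass(GlycanComposition(0, 0)) == 0.0


def test_negative_monosaccharide_count_rejected():
    with pytest.raises(ValueError):
        GlycanComposition(hex=-1, hexnac=4)


@pytest.mark.parametrize(
    "name", ["G0", "G0F", "G1", "G1F", "G1FN", "G1FS", "G2", "G2F", "G2FS", "G0FN"]
)
def test_glycan_short_name_round_trip(name):
    assert GlycanComposition.from_name(name).short_name == name


SIL_BACKBONE = PeptideBackbone("EEQYNSTYR", LabelState.SIL, glyco_site=4)

PRINTED_MZ = [
    ("G0", 2, 1249.502),
    ("G0", 3, 833.337),
    ("G0F", 2, 1322.531),
    ("G0F", 3, 882.023),
    ("G1F", 2, 1403.557),
    ("G1F", 3, 936.041),
]


@pytest.mark.parametrize("glycan,charge,expected", PRINTED_MZ)
def test_sil_glycopeptide_mz(glycan, charge, expected):
    """The SIL IgG1 glycopeptide m/z values observed for the standard."""
    analyte = Analyte(
        id=f"sil-{glycan}",
        backbone=SIL_BACKBONE,
        glycan=GlycanComposition.from_name(glycan),
        charges=(2, 3),
    )
    assert analyte_mz(analyte, charge) == pytest.approx(expected, abs=1e-3)


def test_natural_glycopeptide_mz():
    analyte = Analyte(
        id="nat-G0F",
        backbone=PeptideBackbone("EEQYNSTYR"),
        glycan=GlycanComposition.from_name("G0F"),
        charges=(2,),
    )
    # (1188.5047 + 1444.5339 + 2*1.007276) / 2
    assert analyte_mz(analyte, 2) == pytest.approx(1317.527, abs=1e-3)


def test_sil_minus_natural_mz_equals_label_shift_over_charge():
    for glycan in ("G0", "G0F", "G1F"):
        for z in (2, 3):
            nat = Analyte(
                id="n",
                backbone=PeptideBackbone("EEQYNSTYR"),
                glycan=GlycanComposition.from_name(glycan),
                charges=(2, 3),
            )
            sil = Analyte(
                id="s",
                backbone=SIL_BACKBONE,
                glycan=GlycanComposition.from_name(glycan),
                charges=(2, 3),
            )
            assert sil.mz(z) - nat.mz(z) == pytest.approx(
                sil_mass_shift("R") / z, abs=1e-4
            )


def test_invalid_charge_rejected():
    analyte = Analyte(id="x", backbone=PeptideBackbone("EEQYNSTYR"), charges=(2,))
    with pytest.raises(ValueError):
        analyte.mz(0)


# --- isotopologue pattern vs exhaustive enumeration oracle ----------------


def _oracle_pattern(counts: dict[str, int], prune: float = 1e-13):
    """Exhaustive enumeration over per-element isotope count vectors with
    multinomial probabilities; aggregates by total neutron offset."""
    per_element = []
    for element, n in counts.items():
        isotopes = ISOTOPES[element]
        base = isotopes[0][0]
        dist: dict[int, tuple[float, float]] = {}
        k = len(isotopes)
        for split in itertools.product(range(n + 1), repeat=k - 1):
            rest = n - sum(split)
            if rest < 0:
                continue
            vector = (rest,) + split
            log_prob = math.lgamma(n + 1)
            for count, (_, abundance) in zip(vector, isotopes):
                if count and abundance == 0:
                    log_prob = -math.inf
                    break
                log_prob += count * math.log(abundance) if count else 0.0
                log_prob -= math.lgamma(count + 1)
            prob = math.exp(log_prob) if log_prob > -700 else 0.0
            if prob < prune:
                continue
            offset = sum(
                count * round(mass - base)
                for count, (mass, _) in zip(vector, isotopes)
            )
            mass_total = sum(
                count * (mass - base) for count, (mass, _) in zip(vector, isotopes)
            )
            p_old, m_old = dist.get(offset, (0.0, 0.0))
            dist[offset] = (p_old + prob, m_old + prob * mass_total)
        per_element.append(dist)
    # convolve element distributions
    total: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for dist in per_element:
        new: dict[int, tuple[float, float]] = {}
        for o1, (p1, m1) in total.items():
            for o2, (p2, m2) in dist.items():
                p = p1 * p2
                m = p2 * m1 + p1 * m2  # probability-weighted mass sums
                p_old, m_old = new.get(o1 + o2, (0.0, 0.0))
                new[o1 + o2] = (p_old + p, m_old + m)
        total = new
    mono = sum(ISOTOPES[el][0][0] * n for el, n in counts.items())
    return {
        offset: (p, mono + m / p) for offset, (p, m) in total.items() if p > 0
    }


@pytest.mark.parametrize(
    "counts",
    [
        {"C": 1},
        {"C": 10, "H": 15, "N": 3, "O": 4, "S": 1},
        # natural EEQYNSTYR + G0F glycopeptide
        {"C": 106, "H": 171, "N": 19, "O": 61},
        # SIL equivalent with heavy-Arg pseudo-elements
        {"C": 100, "H": 171, "N": 15, "O": 61, "C13": 6, "N15": 4},
    ],
)
def test_pattern_matches_enumeration_oracle(counts):
    comp = ElementalComposition(counts)
    pattern = isotopologue_pattern(comp, 1.0)
    oracle = _oracle_pattern(counts)
    fast = dict(zip(pattern.offsets.tolist(), pattern.fractions.tolist()))
    offsets = set(fast) | set(oracle)
    tv = 0.5 * sum(
        abs(fast.get(o, 0.0) - (oracle[o][0] if o in oracle else 0.0)) for o in offsets
    )
    assert tv < 1e-9
    for offset, mass in zip(pattern.offsets.tolist(), pattern.masses.tolist()):
        if pattern.fractions[list(pattern.offsets).index(offset)] > 1e-8:
            assert mass == pytest.approx(oracle[offset][1], abs=1e-6)


def test_single_carbon_pattern():
    pattern = isotopologue_pattern(ElementalComposition({"C": 1}), 1.0)
    entries = [(e.offset, round(e.exact_mass, 4), round(e.rel_abundance, 4)) for e in pattern.entries]
    assert entries == [(0, 12.0, 0.9893), (1, 13.0034, 0.0107)]


def test_minimal_covering_prefix():
    comp = peptide_composition(PeptideBackbone("EEQYNSTYR"))
    pattern = isotopologue_pattern(comp, 0.95)
    fractions = pattern.fractions
    assert fractions.sum() >= 0.95
    assert fractions.sum() - fractions.min() < 0.95


def test_empty_composition_rejected():
    with pytest.raises(ValueError):
        isotopologue_pattern(ElementalComposition({}), 1.0)


# --- property tests -------------------------------------------------------

composition_strategy = st.fixed_dictionaries(
    {},
    optional={
        "C": st.integers(1, 60),
        "H": st.integers(1, 90),
        "N": st.integers(0, 15),
        "O": st.integers(0, 25),
        "S": st.integers(0, 3),
    },
).filter(lambda d: sum(d.values()) > 0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(counts=composition_strategy)
def test_full_pattern_sums_to_one(counts):
    pattern = isotopologue_pattern(ElementalComposition(counts), 1.0)
    assert pattern.coverage == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(pattern.offsets) > 0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(counts=composition_strategy, fraction=st.floats(0.5, 0.999))
def test_truncated_pattern_is_minimal_cover(counts, fraction):
    pattern = isotopologue_pattern(ElementalComposition(counts), fraction)
    total = pattern.coverage
    assert total >= fraction - 1e-12
    assert total - pattern.fractions.min() < fraction


@settings(max_examples=25, deadline=None, derandomize=True)
@given(a=composition_strategy, b=composition_strategy)
def test_composition_addition_elementwise(a, b):
    merged = ElementalComposition(a) + ElementalComposition(b)
    for element in set(a) | set(b):
        assert merged.counts.get(element, 0) == a.get(element, 0) + b.get(element, 0)


def test_adding_fucose_keeps_pattern_normalized():
    base = peptide_composition(PeptideBackbone("EEQYNSTYR")) + GlycanComposition.from_name("G0").elemental()
    plus_fuc = base + ElementalComposition({"C": 6, "H": 10, "O": 4})
    p0 = isotopologue_pattern(base, 1.0)
    p1 = isotopologue_pattern(plus_fuc, 1.0)
    assert p1.coverage == pytest.approx(1.0, abs=1e-9)
    assert p1.masses[0] - p0.masses[0] == pytest.approx(146.0579, abs=1e-4)
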