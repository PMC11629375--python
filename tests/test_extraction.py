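"""Background estimation, mass calibration and targeted integration."""

import numpy as np
import pytest

from glycoquant.chem import Analyte, AnalyteRole, GlycanComposition, LabelState, PeptideBackbone
from glycoquant.extraction import (
    CalibrationModel,
    ExtractionConfig,
    analyte_windows,
    estimate_background,
    extract_sample,
    fit_calibration,
    integrate_analyte,
    merge_windows,
)
from glycoquant.panels import build_default_panel
from glycoquant.spectra import Scan, SumSpectrum, sum_spectra

CONFIG = ExtractionConfig()

NAT_BB = PeptideBackbone("EEQYNSTYR", glyco_site=4)
SIL_BB = PeptideBackbone("EEQYNSTYR", LabelState.SIL, glyco_site=4)


def make_analyte(glycan="G0F", sil=False, role=AnalyteRole.QUANTIFIER):
    return Analyte(
        id=f"{'sil' if sil else 'nat'}-{glycan}",
        backbone=SIL_BB if sil else NAT_BB,
        glycan=GlycanComposition.from_name(glycan),
        charges=(2, 3),
        role=role,
    )


def cluster_spectrum(analyte, charge, total=1000.0, emit_fraction=0.9999,
                     ppm_shift=0.0, extra=(), scale_entry=None):
    """Noiseless sum spectrum containing one analyte cluster."""
    pattern = analyte.pattern(emit_fraction)
    mz = pattern.mz(charge) * (1.0 + ppm_shift / 1e6)
    intensity = total * pattern.fractions
    if scale_entry is not None:
        index, factor = scale_entry
        intensity = intensity.copy()
        intensity[index] *= factor
    peaks = sorted(list(zip(mz, intensity)) + list(extra))
    scan = Scan(rt=1.0, mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]))
    return sum_spectra([scan], (0.0, 2.0))


# --- background ------------------------------------------------------------


def test_background_of_flat_noise_floor():
    rng = np.random.default_rng(5)
    mz = np.sort(rng.uniform(990.0, 1010.0, 400))
    intensity = rng.exponential(3.0, 400)
    spectrum = sum_spectra([Scan(rt=1.0, mz=mz, intensity=intensity)], (0.0, 2.0))
    est = estimate_background(spectrum, 1000.0, 10.0)
    k = int(np.ceil(0.2 * spectrum.intensity.size))
    lowest = np.sort(spectrum.intensity)[:k]
    assert est.background == pytest.approx(lowest.mean(), rel=1e-9)
    assert est.noise == pytest.approx(lowest.std(), rel=1e-9)
    assert est.noise > 0 and not est.flagged


def test_background_zero_off_peak_in_noiseless_spectrum():
    analyte = make_analyte()
    spectrum = cluster_spectrum(analyte, 2)
    exclude = analyte_windows(analyte, CONFIG, fraction=0.9999)
    est = estimate_background(spectrum, analyte.mz(2), 10.0, exclude)
    assert est.background == 0.0
    assert est.flagged


def test_background_excludes_analyte_cells():
    analyte = make_analyte()
    rng = np.random.default_rng(6)
    center = analyte.mz(2)
    noise_mz = np.sort(rng.uniform(center - 10, center + 10, 200))
    noise_intensity = rng.exponential(2.0, 200)
    spectrum_noise = sum_spectra(
        [Scan(rt=1.0, mz=noise_mz, intensity=noise_intensity)], (0.0, 2.0)
    )
    pattern = analyte.pattern(0.9999)
    cluster_mz = pattern.mz(2)
    huge = 1e6 * pattern.fractions
    both = sorted(zip(np.concatenate([noise_mz, cluster_mz]),
                      np.concatenate([noise_intensity, huge])))
    spectrum_both = sum_spectra(
        [Scan(rt=1.0, mz=np.array([p[0] for p in both]),
              intensity=np.array([p[1] for p in both]))], (0.0, 2.0)
    )
    exclude = analyte_windows(analyte, CONFIG, fraction=0.9999)
    est_noise = estimate_background(spectrum_noise, center, 10.0, exclude)
    est_both = estimate_background(spectrum_both, center, 10.0, exclude)
    # huge analyte cluster excluded -> estimate driven by the noise only
    assert est_both.background == pytest.approx(est_noise.background, rel=0.2)
    assert est_both.background < 10.0


def test_merge_windows_flattens_overlaps():
    bounds = merge_windows([(1.0, 2.0), (1.5, 3.0), (5.0, 6.0)])
    np.testing.assert_allclose(bounds, [1.0, 3.0, 5.0, 6.0])


# --- calibration -----------------------------------------------------------


def sil_calibrant_panel():
    return [
        Analyte(
            id=f"sil-{g}",
            backbone=SIL_BB,
            glycan=GlycanComposition.from_name(g),
            charges=(2, 3),
            role=AnalyteRole.BOTH,
        )
        for g in ("G0", "G0F", "G1F")
    ]


def calibrant_spectrum(ppm, slope_per_kth=0.0, total=5000.0):
    peaks = []
    for analyte in sil_calibrant_panel():
        pattern = analyte.pattern(0.9999)
        for z in (2, 3):
            mz = pattern.mz(z)
            shift = (ppm + slope_per_kth * (mz - 1000.0) / 1000.0) / 1e6
            peaks.extend(zip(mz * (1.0 + shift), total * pattern.fractions))
    peaks.sort()
    scan = Scan(rt=1.0, mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]))
    return sum_spectra([scan], (0.0, 2.0))


@pytest.mark.parametrize("ppm,slope", [(10.0, 0.0), (-20.0, 0.0), (20.0, 0.0), (5.0, 8.0)])
def test_calibration_recovers_injected_drift(ppm, slope):
    spectrum = calibrant_spectrum(ppm, slope)
    model = fit_calibration(spectrum, sil_calibrant_panel(), CONFIG)
    assert model.kind == "quadratic"
    assert len(model.calibrants_used) == 6
    for analyte in sil_calibrant_panel():
        for z in (2, 3):
            theo = analyte.mz(z)
            observed = theo * (1.0 + (ppm + slope * (theo - 1000.0) / 1000.0) / 1e6)
            residual = (model.apply(observed) - theo) / theo * 1e6
            assert abs(residual) < 1.0


def test_constant_component_recovered():
    spectrum = calibrant_spectrum(10.0)
    model = fit_calibration(spectrum, sil_calibrant_panel(), CONFIG)
    observed = np.array([p.ppm_error for p in model.calibrants_used])
    assert observed.mean() == pytest.approx(10.0, abs=0.5)


def test_identity_on_calibrated_spectrum():
    spectrum = calibrant_spectrum(0.0)
    model = fit_calibration(spectrum, sil_calibrant_panel(), CONFIG)
    for point in model.calibrants_used:
        assert abs(point.ppm_error) < 0.1


def test_all_calibrants_below_sn_gives_none():
    # dense constant floor: apex == background, so S/N = 0 for every calibrant
    rng = np.random.default_rng(3)
    mz = np.sort(rng.uniform(820.0, 1420.0, 4000))
    intensity = np.full(4000, 10.0)
    spectrum = sum_spectra([Scan(rt=1.0, mz=mz, intensity=intensity)], (0.0, 2.0))
    model = fit_calibration(spectrum, sil_calibrant_panel(), CONFIG)
    assert model.kind == "none"
    np.testing.assert_allclose(model.apply(np.array([1000.0])), [1000.0])


def test_apply_invert_round_trip():
    model = CalibrationModel(kind="linear", coefficients=np.array([0.01, -5.0]))
    mz = np.array([850.0, 1200.0, 1400.0])
    np.testing.assert_allclose(model.invert(model.apply(mz)), mz, rtol=1e-10)
    np.testing.assert_allclose(model.apply(model.invert(mz)), mz, rtol=1e-10)


def test_model_order_tiers():
    from glycoquant.extraction import CalibrationPoint, fit_calibration_from_points

    def points(n):
        return [
            CalibrationPoint("a", 2, 1000.0 + i, 1000.0 + i, 5.0 + 0.01 * i, 100.0)
            for i in range(n)
        ]

    assert fit_calibration_from_points(points(0)).kind == "none"
    assert fit_calibration_from_points(points(2)).kind == "constant_ppm"
    assert fit_calibration_from_points(points(4)).kind == "linear"
    assert fit_calibration_from_points(points(6)).kind == "quadratic"


# --- integration -----------------------------------------------------------


@pytest.mark.parametrize("min_fraction", [0.8, 0.9, 0.95, 1.0])
def test_coverage_correction_unbiased_noiseless(min_fraction):
    analyte = make_analyte("G0F")
    spectrum = cluster_spectrum(analyte, 2, total=1000.0)
    result = integrate_analyte(
        spectrum, analyte, 2, config=CONFIG, min_fraction=min_fraction
    )
    assert result.coverage >= min(min_fraction, 0.9999)
    assert result.corrected_area == pytest.approx(1000.0, rel=5e-3)
    assert result.corrected_area >= result.raw_area


def test_empty_spectrum_gives_zero_result():
    analyte = make_analyte()
    spectrum = SumSpectrum(
        mz=np.array([600.0]), intensity=np.array([0.0]), rt_window=(0, 1), source_scan_count=1
    )
    result = integrate_analyte(spectrum, analyte, 2, config=CONFIG)
    assert result.raw_area == 0.0 and result.corrected_area == 0.0 and result.sn == 0.0


def test_ipq_increases_when_pattern_distorted():
    analyte = make_analyte()
    clean = integrate_analyte(cluster_spectrum(analyte, 2), analyte, 2, config=CONFIG)
    distorted = integrate_analyte(
        cluster_spectrum(analyte, 2, scale_entry=(1, 2.0)), analyte, 2, config=CONFIG
    )
    assert clean.ipq < 0.02
    assert distorted.ipq > clean.ipq
    # hand value: doubling isotopologue 1 distorts shares by a known L1 amount
    pattern = analyte.pattern(CONFIG.glyco_min_fraction)
    shares = pattern.fractions / pattern.fractions.sum()
    doubled = shares.copy()
    doubled[1] *= 2
    doubled /= doubled.sum()
    assert distorted.ipq == pytest.approx(np.abs(doubled - shares).sum(), abs=5e-3)


def test_integration_linear_in_intensity():
    analyte = make_analyte()
    low = integrate_analyte(cluster_spectrum(analyte, 2, total=500.0), analyte, 2, config=CONFIG)
    high = integrate_analyte(cluster_spectrum(analyte, 2, total=1000.0), analyte, 2, config=CONFIG)
    assert high.raw_area == pytest.approx(2 * low.raw_area, rel=1e-6)


def test_glycopeptide_uses_calibration_peptide_does_not():
    ppm = 15.0
    glyco = make_analyte()
    spectrum = cluster_spectrum(glyco, 2, ppm_shift=ppm)
    model = CalibrationModel(kind="constant_ppm", coefficients=np.array([ppm]))
    with_cal = integrate_analyte(spectrum, glyco, 2, calibration=model, config=CONFIG)
    without = integrate_analyte(spectrum, glyco, 2, config=CONFIG)
    assert with_cal.calibrated and not without.calibrated
    assert abs(with_cal.ppm_error) < 0.5 < abs(without.ppm_error)

    peptide = Analyte(id="gps", backbone=PeptideBackbone("GPSVFPLAPSSK"), charges=(2,))
    pep_spectrum = cluster_spectrum(peptide, 2, ppm_shift=ppm)
    pep_result = integrate_analyte(pep_spectrum, peptide, 2, calibration=model, config=CONFIG)
    assert not pep_result.calibrated
    assert pep_result.ppm_error == pytest.approx(ppm, abs=1.0)


def test_extract_sample_cardinality_and_order():
    analytes = [make_analyte("G0F"), make_analyte("G0")]
    peaks = []
    for a in analytes:
        pattern = a.pattern(0.9999)
        for z in (2, 3):
            peaks.extend(zip(pattern.mz(z), 1000 * pattern.fractions))
    peaks.sort()
    spectrum = sum_spectra(
        [Scan(rt=1.0, mz=np.array([p[0] for p in peaks]),
              intensity=np.array([p[1] for p in peaks]))], (0.0, 2.0)
    )
    results = extract_sample(spectrum, analytes, CONFIG)
    assert len(results) == 4
    assert [(r.analyte_id, r.charge) for r in results] == [
        ("nat-G0", 2), ("nat-G0", 3), ("nat-G0F", 2), ("nat-G0F", 3)
    ]
    permuted = extract_sample(spectrum, analytes[::-1], CONFIG)
    assert [(r.analyte_id, r.charge, r.corrected_area) for r in permuted] == [
        (r.analyte_id, r.charge, r.corrected_area) for r in results
    ]


def test_empty_panel_rejected():
    spectrum = SumSpectrum(np.array([1000.0]), np.array([1.0]), (0, 1), 1)
    with pytest.raises(ValueError):
        extract_sample(spectrum, [], CONFIG)


def test_same_glycoform_clusters_never_share_windows():
    """Heavy fucosylated cluster sits between natural fucosylated and
    natural afucosylated clusters without window overlap at z = 2, 3."""
    for fuc_name, afuc_name in [("G0F", "G0"), ("G1F", "G1")]:
        trio = [
            make_analyte(fuc_name, sil=False),
            make_analyte(fuc_name, sil=True),
            make_analyte(afuc_name, sil=False),
        ]
        for z in (2, 3):
            window_sets = []
            for analyte in trio:
                windows = analyte_windows(analyte, CONFIG, charges=(z,))
                window_sets.append(windows)
            for i in range(3):
                for j in range(i + 1, 3):
                    for lo1, hi1 in window_sets[i]:
                        for lo2, hi2 in window_sets[j]:
                            assert hi1 < lo2 or hi2 < lo1
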