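"""Mass calibration and targeted isotopologue integration of sum spectra.

Each analyte's isotopologue cluster is integrated inside narrow m/z windows
around its theoretical aggregated isotopologue positions, after recalibrating
against SIL glycopeptide calibrants.  Quality metrics follow the conventions
of targeted glycopeptide processing:

* ``coverage`` — summed theoretical fraction of the integrated isotopologues;
  the raw area is divided by it to estimate the full-cluster abundance.
* ``ipq`` (isotopic pattern quality) — L1 distance between observed and
  theoretical normalized isotopologue intensities (lower is better).
* ``sn`` — apex intensity of the most abundant isotopologue over the local
  noise standard deviation.

Background and noise are estimated from the lowest-intensity 20% of observed
grid peaks in a wide window around each cluster, excluding every targeted
integration window; the mean of that quantile is subtracted once per observed
peak inside an integration window.  This estimator suits sparse centroided
data, where empty grid cells carry no baseline.

Glycopeptides are integrated in the calibrated m/z frame; non-glycosylated
peptides are deliberately integrated without calibration, with their own
wider window and looser pattern fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem import Analyte, AnalyteRole, IsotopologuePattern, PROTON_MASS
from .spectra import SumSpectrum

__all__ = [
    "ExtractionConfig",
    "NoiseEstimate",
    "CalibrationPoint",
    "CalibrationModel",
    "ExtractionResult",
    "estimate_background",
    "fit_calibration",
    "calibration_points",
    "fit_calibration_from_points",
    "integrate_analyte",
    "extract_sample",
    "analyte_windows",
    "merge_windows",
]


@dataclass
class ExtractionConfig:
    """Integration and calibration parameters (all units Th unless noted)."""

    glyco_window_th: float = 0.04
    glyco_min_fraction: float = 0.95
    pep_window_th: float = 0.065
    pep_min_fraction: float = 0.8
    calibrant_sn: float = 9.0
    ppm_search: float = 30.0
    noise_half_width_th: float = 10.0

    def window_for(self, analyte: Analyte) -> float:
        return self.glyco_window_th if analyte.is_glyco else self.pep_window_th

    def min_fraction_for(self, analyte: Analyte) -> float:
        return self.glyco_min_fraction if analyte.is_glyco else self.pep_min_fraction


@dataclass
class NoiseEstimate:
    background: float
    noise: float
    flagged: bool = False


@dataclass
class CalibrationPoint:
    analyte_id: str
    charge: int
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    sn: float


@dataclass
class CalibrationModel:
    """Observed ppm error as a polynomial in m/z.

    ``apply`` maps an observed m/z into the calibrated frame; ``invert`` maps
    a theoretical m/z to where it should appear in the uncalibrated spectrum.
    """

    kind: str  # none | constant_ppm | linear | quadratic
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(1))
    calibrants_used: list[CalibrationPoint] = field(default_factory=list)

    def ppm(self, mz):
        if self.kind == "none":
            return np.zeros_like(np.asarray(mz, dtype=float))
        return np.polyval(self.coefficients, mz)

    def apply(self, mz):
        return np.asarray(mz, dtype=float) / (1.0 + self.ppm(mz) / 1e6)

    def invert(self, mz_calibrated):
        x = np.asarray(mz_calibrated, dtype=float)
        for _ in range(8):  # fixed point; converges far below 1e-9 relative
            x = mz_calibrated * (1.0 + self.ppm(x) / 1e6)
        return x


@dataclass
class ExtractionResult:
    analyte_id: str
    charge: int
    raw_area: float
    coverage: float
    corrected_area: float
    sn: float
    ppm_error: float
    ipq: float
    calibrated: bool
    background: float = 0.0
    noise: float = 0.0


def merge_windows(windows: Iterable[tuple[float, float]]) -> np.ndarray:
    """Merge overlapping (lo, hi) intervals into a flat sorted bound array."""
    intervals = sorted(windows)
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return np.array([b for pair in merged for b in pair])


# fraction of the theoretical pattern masked out of background estimation;
# wider than any integration subset so faint cluster tails are not mistaken
# for baseline
_EXCLUDE_FRACTION = 0.9999


def analyte_windows(
    analyte: Analyte,
    config: ExtractionConfig,
    charges: Optional[Sequence[int]] = None,
    fraction: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Theoretical integration windows of an analyte's selected isotopologues."""
    half = config.window_for(analyte)
    pattern = analyte.pattern(fraction or config.min_fraction_for(analyte))
    out = []
    for z in charges if charges is not None else analyte.charges:
        for mz in pattern.mz(z):
            out.append((mz - half, mz + half))
    return out


def estimate_background(
    spectrum: SumSpectrum,
    center_mz: float,
    half_width: float = 10.0,
    exclude_windows: Sequence[tuple[float, float]] = (),
) -> NoiseEstimate:
    """Local background and noise from the lowest-intensity 20% of peaks.

    Peaks inside any targeted integration window are excluded so analyte
    signal does not inflate the estimate.  A window devoid of usable peaks
    yields background 0 with the smallest positive spectrum intensity as a
    flagged noise stand-in.
    """
    sel = spectrum.slice(center_mz - half_width, center_mz + half_width)
    mz = spectrum.mz[sel]
    intensity = spectrum.intensity[sel]
    if len(exclude_windows) and mz.size:
        bounds = merge_windows(exclude_windows)
        inside = np.searchsorted(bounds, mz) % 2 == 1
        mz, intensity = mz[~inside], intensity[~inside]
    if intensity.size == 0:
        positives = spectrum.intensity[spectrum.intensity > 0]
        fallback = float(positives.min()) if positives.size else 0.0
        return NoiseEstimate(0.0, fallback, flagged=True)
    k = max(1, int(np.ceil(0.2 * intensity.size)))
    lowest = np.sort(intensity)[:k]
    background = float(lowest.mean())
    noise = float(lowest.std())
    return NoiseEstimate(background, noise, flagged=noise <= 0)


def _apex(mz: np.ndarray, intensity: np.ndarray, center: float) -> int:
    """Index of the most intense peak; ties broken by smaller |m/z - center|."""
    top = intensity.max()
    candidates = np.flatnonzero(intensity == top)
    return int(candidates[np.argmin(np.abs(mz[candidates] - center))])


def calibration_points(
    spectrum: SumSpectrum,
    calibrants: Sequence[Analyte],
    config: ExtractionConfig,
) -> list[CalibrationPoint]:
    """Match calibrant monoisotopic peaks and keep those above the S/N cutoff."""
    exclude = []
    for analyte in calibrants:
        exclude.extend(analyte_windows(analyte, config, fraction=_EXCLUDE_FRACTION))
    points: list[CalibrationPoint] = []
    for analyte in calibrants:
        for z in analyte.charges:
            theo = analyte.mz(z)
            tol = theo * config.ppm_search / 1e6
            sel = spectrum.slice(theo - tol, theo + tol)
            mz = spectrum.mz[sel]
            intensity = spectrum.intensity[sel]
            if mz.size == 0:
                continue
            i = _apex(mz, intensity, theo)
            est = estimate_background(
                spectrum, theo, config.noise_half_width_th, exclude
            )
            if est.noise > 0:
                sn = (float(intensity[i]) - est.background) / est.noise
            else:
                sn = np.inf if intensity[i] > est.background else 0.0
            if sn >= config.calibrant_sn:
                observed = float(mz[i])
                points.append(
                    CalibrationPoint(
                        analyte_id=analyte.id,
                        charge=z,
                        theoretical_mz=theo,
                        observed_mz=observed,
                        ppm_error=(observed - theo) / theo * 1e6,
                        sn=float(sn),
                    )
                )
    return points


def fit_calibration_from_points(points: Sequence[CalibrationPoint]) -> CalibrationModel:
    """Tiered polynomial fit of ppm error vs m/z: >=5 points quadratic,
    3-4 linear, 1-2 constant, 0 none (uncalibrated, flagged downstream)."""
    n = len(points)
    if n == 0:
        return CalibrationModel(kind="none")
    x = np.array([p.observed_mz for p in points])
    y = np.array([p.ppm_error for p in points])
    if n >= 5:
        kind, degree = "quadratic", 2
    elif n >= 3:
        kind, degree = "linear", 1
    else:
        kind, degree = "constant_ppm", 0
    coeffs = np.polyfit(x, y, degree) if degree else np.array([y.mean()])
    return CalibrationModel(kind=kind, coefficients=coeffs, calibrants_used=list(points))


def fit_calibration(
    spectrum: SumSpectrum,
    calibrants: Sequence[Analyte],
    config: Optional[ExtractionConfig] = None,
) -> CalibrationModel:
    config = config or ExtractionConfig()
    usable = [
        a for a in calibrants if a.role in (AnalyteRole.CALIBRANT, AnalyteRole.BOTH)
    ] or list(calibrants)
    return fit_calibration_from_points(calibration_points(spectrum, usable, config))


def integrate_analyte(
    spectrum: SumSpectrum,
    analyte: Analyte,
    charge: int,
    calibration: Optional[CalibrationModel] = None,
    config: Optional[ExtractionConfig] = None,
    window_th: Optional[float] = None,
    min_fraction: Optional[float] = None,
    exclude_windows: Optional[Sequence[tuple[float, float]]] = None,
) -> ExtractionResult:
    """Integrate one analyte charge state from a sum spectrum.

    Only glycopeptides use the calibration model; non-glycosylated peptides
    are integrated in the raw m/z frame regardless of the model.
    """
    config = config or ExtractionConfig()
    if window_th is None:
        window_th = config.window_for(analyte)
    if min_fraction is None:
        min_fraction = config.min_fraction_for(analyte)
    if window_th <= 0:
        raise ValueError("window_th must be positive")

    use_calibration = calibration is not None and analyte.is_glyco
    model = calibration if use_calibration else CalibrationModel(kind="none")

    pattern = analyte.pattern(min_fraction)
    theo_mz = pattern.mz(charge)
    centers = np.asarray(model.invert(theo_mz))  # windows in the observed frame
    if exclude_windows is None:
        exclude_windows = [(c - window_th, c + window_th) for c in centers]

    est = estimate_background(
        spectrum, float(centers[0]), config.noise_half_width_th, exclude_windows
    )

    fractions = pattern.fractions
    areas = np.zeros(len(centers))
    devs = np.full(len(centers), np.nan)
    apex_intensity = np.zeros(len(centers))
    for i, center in enumerate(centers):
        sel = spectrum.slice(center - window_th, center + window_th)
        mz = spectrum.mz[sel]
        intensity = spectrum.intensity[sel]
        if mz.size == 0:
            continue
        areas[i] = max(float(intensity.sum()) - est.background * mz.size, 0.0)
        j = _apex(mz, intensity, center)
        apex_intensity[i] = float(intensity[j])
        devs[i] = (float(mz[j]) - center) / center * 1e6

    raw_area = float(areas.sum())
    coverage = pattern.coverage
    corrected_area = raw_area / coverage if coverage > 0 else 0.0

    top = int(np.argmax(fractions))
    if apex_intensity[top] > 0:
        if est.noise > 0:
            sn = (apex_intensity[top] - est.background) / est.noise
        else:
            sn = np.inf if apex_intensity[top] > est.background else 0.0
    else:
        sn = 0.0

    observed = ~np.isnan(devs)
    if observed.any() and fractions[observed].sum() > 0:
        weights = fractions[observed] / fractions[observed].sum()
        ppm_error = float(np.sum(weights * devs[observed]))
    else:
        ppm_error = np.nan

    if raw_area > 0:
        obs_share = areas / raw_area
        theo_share = fractions / fractions.sum()
        ipq = float(np.abs(obs_share - theo_share).sum())
    else:
        ipq = 0.0

    return ExtractionResult(
        analyte_id=analyte.id,
        charge=charge,
        raw_area=raw_area,
        coverage=float(coverage),
        corrected_area=corrected_area,
        sn=float(sn),
        ppm_error=ppm_error,
        ipq=ipq,
        calibrated=use_calibration and model.kind != "none",
        background=est.background,
        noise=est.noise,
    )


def extract_sample(
    spectrum: SumSpectrum,
    panel: Sequence[Analyte],
    config: Optional[ExtractionConfig] = None,
    calibration: Optional[CalibrationModel] = None,
) -> list[ExtractionResult]:
    """Integrate every (analyte, charge) of a panel against one sum spectrum.

    All targeted windows of the panel are excluded from background estimation
    for every analyte.  Results are ordered by analyte id, then charge.
    """
    if not panel:
        raise ValueError("empty analyte panel")
    config = config or ExtractionConfig()
    model = calibration or CalibrationModel(kind="none")
    exclude: list[tuple[float, float]] = []
    for analyte in panel:
        if analyte.role is AnalyteRole.EXCLUDED:
            continue
        half = config.window_for(analyte)
        pattern = analyte.pattern(_EXCLUDE_FRACTION)
        for z in analyte.charges:
            centers = model.invert(pattern.mz(z)) if analyte.is_glyco else pattern.mz(z)
            exclude.extend((c - half, c + half) for c in np.atleast_1d(centers))
    results = []
    for analyte in sorted(panel, key=lambda a: a.id):
        if analyte.role is AnalyteRole.EXCLUDED:
            continue
        for z in sorted(analyte.charges):
            results.append(
                integrate_analyte(
                    spectrum,
                    analyte,
                    z,
                    calibration=calibration,
                    config=config,
                    exclude_windows=exclude,
                )
            )
    return results
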