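"""Synthetic LC-MS cohort generator with full ground truth.

Emulates the study conditions of a SIL-spiked antigen-specific IgG cohort:
cases with anti-S IgG1 concentrations log-uniform over the quantitation
range, 28 antibody-deficient negative controls contributing only residual
background, and pooled replicate samples for precision assessment.  Each
sample yields centroided MS1 scans in which every targeted (glyco)peptide
appears as its truncated isotopologue cluster at each charge state, shifted
by a configurable miscalibration model, perturbed by multiplicative
intensity noise, distributed over the scans of its retention window by a
fixed triangular chromatographic profile, and embedded in a low-intensity
noise floor with optional contaminant peaks.

Intensity response is linear in analyte amount with a single response factor
shared by natural and SIL species — the core assumption of ratio-based
quantitation with an isotopologue standard.  The truth table is sufficient
to score every downstream module without re-reading the spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Analyte, LabelState
from .curation import Role, SampleMeta, write_metadata_tsv
from .panels import (
    DEFAULT_IGG1_GLYCOFORMS,
    DEFAULT_IGG3_GLYCOFORMS,
    SIL_GLYCOFORMS,
    build_default_panel,
)
from .quantitation import SpikeConfig
from .spectra import Scan, write_mzxml, write_peaklist_tsv, write_table

__all__ = [
    "NoiseConfig",
    "MiscalConfig",
    "InterferenceConfig",
    "SimConfig",
    "SampleTruth",
    "draw_truth",
    "simulate_sample",
    "iter_cohort",
    "simulate_cohort",
]

#: Fraction of the theoretical isotopologue pattern emitted per cluster.
_EMIT_FRACTION = 0.9999

#: Fixed triangular chromatographic profile over the scans of a window.
_CHROM_WEIGHTS = np.array([1, 2, 3, 4, 5, 5, 4, 3, 2, 1], dtype=float)


@dataclass(frozen=True)
class NoiseConfig:
    multiplicative_cv: float = 0.05   # per-peak lognormal intensity noise
    floor_intensity: float = 3.0      # mean intensity of noise-floor peaks
    floor_density_per_th: float = 1.0  # noise peaks per Th per scan


@dataclass(frozen=True)
class MiscalConfig:
    """Mass miscalibration in ppm as a linear function of m/z."""

    constant_ppm: float = 3.0
    slope_ppm_per_kth: float = 0.0  # additional ppm per 1000 Th above 1000

    def ppm(self, mz):
        return self.constant_ppm + self.slope_ppm_per_kth * (np.asarray(mz) - 1000.0) / 1000.0


@dataclass(frozen=True)
class InterferenceConfig:
    rate: float = 2.0          # expected contaminant peaks per sample
    intensity: float = 50.0    # intensity scale of contaminants


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cases: int = 50
    n_negatives: int = 28
    n_pool_replicates: int = 19
    conc_range_ng_ml: tuple[float, float] = (100.0, 10000.0)
    pool_conc_ng_ml: float = 5400.0
    profile_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IGG1_GLYCOFORMS)
    )
    profile_concentration: float = 2000.0  # Dirichlet precision of per-sample profiles
    sil_profile: dict[str, float] = field(default_factory=lambda: dict(SIL_GLYCOFORMS))
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    response_factor: float = 1000.0  # intensity units per ng
    charge_split: dict[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    miscal: MiscalConfig = field(default_factory=MiscalConfig)
    interference: InterferenceConfig = field(default_factory=InterferenceConfig)
    negative_background_median: float = 0.005
    negative_background_sigma: float = 0.5
    include_igg3: bool = False
    igg3_fraction_of_igg1: float = 0.1
    igg3_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IGG3_GLYCOFORMS)
    )
    scans_per_window: int = 10
    groups: tuple[str, ...] = ("EMC", "LUMC", "MUMC", "UMCG")

    def __post_init__(self) -> None:
        total = sum(self.profile_means.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile means must sum to 1, got {total}")
        if any(v < 0 for v in self.profile_means.values()):
            raise ValueError("negative profile mean")
        lo, hi = self.conc_range_ng_ml
        if not 0 < lo < hi:
            raise ValueError("invalid concentration range")


@dataclass
class SampleTruth:
    sample_id: str
    role: Role
    group: str
    batch: str
    true_conc_ng_ml: float          # effective natural IgG1 concentration
    profile: dict[str, float]        # natural IgG1 glycoform fractions
    background_ratio: float          # nat/SIL ratio for negative controls
    igg3_conc_ng_ml: float

    def as_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "role": self.role.value,
            "group": self.group,
            "batch": self.batch,
            "true_conc_ng_ml": self.true_conc_ng_ml,
            "background_ratio": self.background_ratio,
            "igg3_conc_ng_ml": self.igg3_conc_ng_ml,
        }
        for name, fraction in self.profile.items():
            row[f"profile_{name}"] = fraction
        return row


def draw_truth(
    sample_id: str, role: Role, group: str, batch: str, config: SimConfig,
    rng: np.random.Generator,
) -> SampleTruth:
    names = sorted(config.profile_means)
    means = np.array([config.profile_means[n] for n in names])
    if role is Role.POOL_REPLICATE:
        conc = config.pool_conc_ng_ml
        profile = dict(zip(names, means))
        background = 0.0
    elif role is Role.NEGATIVE_CONTROL:
        background = float(
            np.exp(
                np.log(config.negative_background_median)
                + config.negative_background_sigma * rng.standard_normal()
            )
        )
        # residual natural signal expressed as an effective concentration
        conc = background * config.spike.scale
        profile = dict(zip(names, means))
    else:
        lo, hi = config.conc_range_ng_ml
        conc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        alpha = means * config.profile_concentration
        profile = dict(zip(names, rng.dirichlet(np.where(alpha > 0, alpha, 1e-6))))
        background = 0.0
    igg3 = conc * config.igg3_fraction_of_igg1 if config.include_igg3 else 0.0
    return SampleTruth(sample_id, role, group, batch, conc, profile, background, igg3)


def _amount_ng(analyte: Analyte, truth: SampleTruth, config: SimConfig) -> float:
    """Ground-truth analyte amount in ng for one sample."""
    nat_total = truth.true_conc_ng_ml * config.spike.plasma_volume_ml
    if analyte.id.startswith("IgG1-") and analyte.is_glyco:
        name = analyte.glycan.short_name
        if analyte.backbone.label_state is LabelState.SIL:
            return config.spike.sil_mass_ng * config.sil_profile.get(name, 0.0)
        return nat_total * truth.profile.get(name, 0.0)
    if analyte.id.startswith("IgG3-"):
        igg3_total = truth.igg3_conc_ng_ml * config.spike.plasma_volume_ml
        return igg3_total * config.igg3_profile.get(analyte.glycan.short_name, 0.0)
    # non-glycosylated proteotypic peptides scale with the whole protein
    if analyte.backbone.label_state is LabelState.SIL:
        return config.spike.sil_mass_ng
    return nat_total


def simulate_sample(
    truth: SampleTruth,
    panel: Sequence[Analyte],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Scan]:
    """Emit the centroided MS1 scans of one sample."""
    windows = sorted({a.rt_window for a in panel})
    n_scans = config.scans_per_window
    weights = _CHROM_WEIGHTS[:n_scans].copy()
    if len(weights) < n_scans:
        weights = np.interp(
            np.linspace(0, 1, n_scans), np.linspace(0, 1, len(_CHROM_WEIGHTS)), _CHROM_WEIGHTS
        )
    weights = weights / weights.sum()

    # m/z band of each window, padded so the noise floor covers the
    # background-estimation range around every cluster
    bands: dict[tuple[float, float], tuple[float, float]] = {}
    for window in windows:
        mzs = []
        for a in panel:
            if a.rt_window != window:
                continue
            pattern = a.pattern(_EMIT_FRACTION)
            for z in a.charges:
                mzs.extend(pattern.mz(z))
        bands[window] = (min(mzs) - 12.0, max(mzs) + 12.0)

    peaks_per_scan: dict[tuple[tuple[float, float], int], list[tuple[float, float]]] = {
        (w, i): [] for w in windows for i in range(n_scans)
    }

    cv = config.noise.multiplicative_cv
    for analyte in sorted(panel, key=lambda a: a.id):
        amount = _amount_ng(analyte, truth, config)
        if amount <= 0:
            continue
        total_intensity = amount * config.response_factor
        pattern = analyte.pattern(_EMIT_FRACTION)
        for z in sorted(analyte.charges):
            share = config.charge_split.get(z, 0.0) if analyte.is_glyco else 1.0
            if share <= 0:
                continue
            theo = pattern.mz(z)
            observed = theo * (1.0 + config.miscal.ppm(theo) / 1e6)
            cluster = total_intensity * share * pattern.fractions
            if cv > 0:
                factors = np.exp(
                    cv * rng.standard_normal(cluster.size) - 0.5 * cv * cv
                )
                cluster = cluster * factors
            for i in range(n_scans):
                peaks_per_scan[(analyte.rt_window, i)].extend(
                    zip(observed, cluster * weights[i])
                )

    # contaminant peaks: persistent within one window, random m/z
    n_contaminants = rng.poisson(config.interference.rate)
    for _ in range(n_contaminants):
        window = windows[rng.integers(len(windows))]
        lo, hi = bands[window]
        mz = rng.uniform(lo, hi)
        intensity = config.interference.intensity * rng.exponential()
        for i in range(n_scans):
            peaks_per_scan[(window, i)].append((mz, intensity * weights[i]))

    # noise floor
    floor = config.noise.floor_intensity
    density = config.noise.floor_density_per_th
    scans = []
    for window in windows:
        start, end = window
        rts = start + (np.arange(n_scans) + 0.5) / n_scans * (end - start)
        lo, hi = bands[window]
        for i in range(n_scans):
            peaks = peaks_per_scan[(window, i)]
            if floor > 0 and density > 0:
                n_noise = rng.poisson(density * (hi - lo))
                noise_mz = rng.uniform(lo, hi, n_noise)
                noise_intensity = rng.exponential(floor, n_noise)
                peaks = peaks + list(zip(noise_mz, noise_intensity))
            if not peaks:
                peaks = [(lo, 0.0)]
            mz = np.array([p[0] for p in peaks])
            intensity = np.array([p[1] for p in peaks])
            scans.append(Scan(rt=float(rts[i]), mz=mz, intensity=intensity))
    scans.sort(key=lambda s: s.rt)
    return scans


def _cohort_members(config: SimConfig) -> list[tuple[str, Role, str, str]]:
    members = []
    for i in range(config.n_cases):
        group = config.groups[i % len(config.groups)]
        batch = f"batch{i % 4 + 1}"
        members.append((f"case_{i + 1:03d}", Role.CASE, group, batch))
    for i in range(config.n_negatives):
        members.append((f"neg_{i + 1:03d}", Role.NEGATIVE_CONTROL, "", f"batch{i % 4 + 1}"))
    for i in range(config.n_pool_replicates):
        members.append((f"pool_{i + 1:03d}", Role.POOL_REPLICATE, "pool", f"batch{i % 4 + 1}"))
    return members


def iter_cohort(
    config: SimConfig, panel: Optional[Sequence[Analyte]] = None
) -> Iterator[tuple[SampleMeta, SampleTruth, list[Scan]]]:
    """Generate the cohort sample by sample (deterministic under the seed)."""
    if panel is None:
        panel = build_default_panel(include_igg3=config.include_igg3)
    for index, (sample_id, role, group, batch) in enumerate(_cohort_members(config)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
        truth = draw_truth(sample_id, role, group, batch, config, rng)
        scans = simulate_sample(truth, panel, config, rng)
        yield SampleMeta(sample_id, role, group, batch), truth, scans


def simulate_cohort(
    config: SimConfig,
    outdir: Optional[str | Path] = None,
    panel: Optional[Sequence[Analyte]] = None,
    fmt: str = "mzxml",
) -> tuple[list[SampleMeta], pd.DataFrame, Optional[list[Path]]]:
    """Generate the full cohort; optionally write one spectrum file per
    sample plus metadata and ground-truth tables.

    Returns (metadata, truth table, file paths or None).
    """
    if fmt not in ("mzxml", "tsv"):
        raise ValueError("fmt must be 'mzxml' or 'tsv'")
    metas: list[SampleMeta] = []
    truth_rows = []
    paths: Optional[list[Path]] = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
    for meta, truth, scans in iter_cohort(config, panel):
        metas.append(meta)
        truth_rows.append(truth.as_row())
        if outdir is not None:
            path = outdir / f"{meta.sample_id}.{ 'mzxml' if fmt == 'mzxml' else 'tsv'}"
            if fmt == "mzxml":
                write_mzxml(path, scans)
            else:
                write_peaklist_tsv(path, scans)
            paths.append(path)
    truth_df = pd.DataFrame(truth_rows)
    if outdir is not None:
        write_metadata_tsv(outdir / "metadata.tsv", metas)
        write_table(truth_df, outdir / "truth.tsv", "truth")
    return metas, truth_df, paths
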