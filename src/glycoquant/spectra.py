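"""Spectrum I/O and retention-time-windowed sum spectra.

Reads centroided MS1 scans from mzXML (via pyteomics) or from a simple TSV
peak-list dialect used for text fixtures, and merges the scans of a retention
window into a single sum spectrum on a fixed fine m/z grid.  The merge grid
(0.002 Th by default) is an order of magnitude finer than the narrowest
integration window, so merging cannot move signal across integration
boundaries.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mzxml as _mzxml

__all__ = [
    "Scan",
    "SumSpectrum",
    "read_mzxml",
    "write_mzxml",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "read_scans",
    "sum_spectra",
    "write_table",
    "read_table",
    "DEFAULT_GRID_TH",
]

DEFAULT_GRID_TH = 0.002


@dataclass
class Scan:
    """One centroided scan: sorted m/z array with parallel intensities."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class SumSpectrum:
    """Grid-merged sum of the MS1 scans inside one retention window."""

    mz: np.ndarray
    intensity: np.ndarray
    rt_window: tuple[float, float]
    source_scan_count: int
    grid: float = DEFAULT_GRID_TH

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def slice(self, lo: float, hi: float) -> slice:
        """Index slice of peaks with lo <= m/z <= hi."""
        i = int(np.searchsorted(self.mz, lo, side="left"))
        j = int(np.searchsorted(self.mz, hi, side="right"))
        return slice(i, j)


def read_mzxml(path: str | Path) -> list[Scan]:
    """Read all scans from an mzXML file, ordered by retention time.

    Supports uncompressed and zlib-compressed 32/64-bit peak arrays.  A
    malformed scan raises a ValueError naming the scan number.
    """
    scans: list[Scan] = []
    with _mzxml.read(str(path)) as reader:
        for entry in reader:
            num = entry.get("num", "?")
            try:
                rt_value = entry["retentionTime"]
                rt = float(rt_value)
                # pyteomics reports mzXML retention time in minutes
                if getattr(rt_value, "unit_info", "minute") == "minute":
                    rt *= 60.0
                level = int(entry["msLevel"])
                mz = np.asarray(entry["m/z array"], dtype=float)
                inten = np.asarray(entry["intensity array"], dtype=float)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise ValueError(f"malformed mzXML scan {num} in {path}: {exc}") from exc
            scans.append(Scan(rt=rt, mz=mz, intensity=inten, ms_level=level))
    scans.sort(key=lambda s: s.rt)
    return scans


def write_mzxml(
    path: str | Path,
    scans: Sequence[Scan],
    precision: int = 32,
    compress: bool = False,
) -> None:
    """Write scans as minimal mzXML 3.2 with base64 network-order peaks."""
    if precision not in (32, 64):
        raise ValueError("precision must be 32 or 64")
    fmt = ">%d%s"
    code = "f" if precision == 32 else "d"
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for i, scan in enumerate(scans, start=1):
        interleaved = np.empty(2 * scan.mz.size)
        interleaved[0::2] = scan.mz
        interleaved[1::2] = scan.intensity
        raw = struct.pack(fmt % (interleaved.size, code), *interleaved)
        if compress:
            raw = zlib.compress(raw)
        payload = base64.b64encode(raw).decode("ascii")
        compression = ' compressionType="zlib"' if compress else ' compressionType="none"'
        lines.append(
            f'  <scan num="{i}" msLevel="{scan.ms_level}" peaksCount="{scan.mz.size}"'
            f' retentionTime="PT{scan.rt:.4f}S">'
        )
        lines.append(
            f'   <peaks precision="{precision}" byteOrder="network"'
            f' contentType="m/z-int"{compression}'
            f' compressedLen="{len(raw) if compress else 0}">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    Path(path).write_text("\n".join(lines))


_PEAKLIST_COLUMNS = ["mz", "intensity", "rt", "ms_level"]


def read_peaklist_tsv(path: str | Path) -> list[Scan]:
    """Read the TSV peak-list dialect (columns mz, intensity, rt, ms_level)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak list {path} missing columns: {missing}")
    scans = []
    for (rt, level), chunk in df.groupby(["rt", "ms_level"], sort=True):
        scans.append(
            Scan(
                rt=float(rt),
                mz=chunk["mz"].to_numpy(),
                intensity=chunk["intensity"].to_numpy(),
                ms_level=int(level),
            )
        )
    scans.sort(key=lambda s: s.rt)
    return scans


def write_peaklist_tsv(path: str | Path, scans: Sequence[Scan]) -> None:
    frames = []
    for scan in scans:
        frames.append(
            pd.DataFrame(
                {
                    "mz": scan.mz,
                    "intensity": scan.intensity,
                    "rt": scan.rt,
                    "ms_level": scan.ms_level,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_PEAKLIST_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write("# glycoquant peaklist table v1\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_scans(path: str | Path) -> list[Scan]:
    """Dispatch on file suffix: .mzxml / .mzXML or .tsv peak list."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mzxml":
        return read_mzxml(path)
    if suffix == ".tsv":
        return read_peaklist_tsv(path)
    raise ValueError(f"unsupported spectrum file type: {path}")


def sum_spectra(
    scans: Iterable[Scan],
    rt_window: tuple[float, float],
    grid: float = DEFAULT_GRID_TH,
) -> SumSpectrum:
    """Merge all MS1 scans inside a retention window into one sum spectrum.

    Centroids are binned on a fixed grid of width ``grid`` Th; intensities
    are summed per cell and the cell m/z is the intensity-weighted mean of
    its contributing centroids.  Deterministic for fixed input.
    """
    start, end = rt_window
    if not start < end:
        raise ValueError(f"invalid rt window: {rt_window}")
    scans = list(scans)
    selected = [s for s in scans if s.ms_level == 1 and start <= s.rt <= end]
    if not selected:
        rts = [s.rt for s in scans if s.ms_level == 1]
        available = f"{min(rts):.1f}-{max(rts):.1f} s" if rts else "none"
        raise ValueError(
            f"no MS1 scans in rt window {start}-{end} s (available: {available})"
        )
    mz = np.concatenate([s.mz for s in selected])
    intensity = np.concatenate([s.intensity for s in selected])
    if mz.size == 0:
        return SumSpectrum(mz, intensity, rt_window, len(selected), grid)
    cells = np.floor(mz / grid).astype(np.int64)
    uniq, inverse = np.unique(cells, return_inverse=True)
    summed = np.bincount(inverse, weights=intensity, minlength=uniq.size)
    weighted = np.bincount(inverse, weights=mz * intensity, minlength=uniq.size)
    counts = np.bincount(inverse, minlength=uniq.size)
    plain = np.bincount(inverse, weights=mz, minlength=uniq.size)
    # zero-intensity cells fall back to the plain mean m/z
    merged_mz = np.where(summed > 0, weighted / np.where(summed > 0, summed, 1), plain / counts)
    return SumSpectrum(merged_mz, summed, rt_window, len(selected), grid)


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    """Write a result table as TSV with a schema-version comment line."""
    with open(path, "w") as fh:
        fh.write(f"# glycoquant {name} table v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
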