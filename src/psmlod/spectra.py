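"""DTA/MGF spectrum parsing, noise filtering, and spectrum-level quantities."""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .chem import PROTON

__all__ = [
    "Spectrum",
    "parse_dta",
    "load_dta_directory",
    "parse_mgf",
    "noise_filter",
    "peak_density",
    "top_intense_peaks",
]

#: Average residue mass used to estimate sequence length from precursor mass.
AVERAGE_RESIDUE_MASS = 114.0


@dataclass
class Spectrum:
    """One MS/MS spectrum.

    ``precursor_mh`` is the singly protonated precursor mass as stored on
    the first line of a DTA file; ``neutral_mass = precursor_mh - proton``.
    Peaks are kept in descending-intensity order (ties broken by ascending
    m/z) from the moment of construction.
    """

    source_file: str
    precursor_mh: float
    parent_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def neutral_mass(self) -> float:
        return self.precursor_mh - PROTON

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_peaks(
        cls,
        precursor_mh: float,
        parent_charge: int,
        mz,
        intensity,
        source_file: str = "<memory>",
    ) -> "Spectrum":
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        order = np.lexsort((mz, -intensity))
        return cls(source_file, float(precursor_mh), int(parent_charge),
                   mz[order].copy(), intensity[order].copy())


def parse_dta(content: str, source_file: str = "<memory>") -> Spectrum:
    """Parse DTA text: first line 'M+H charge', then 'm/z intensity' lines."""
    lines = [ln.strip() for ln in content.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"{source_file}: empty DTA file")
    header = lines[0].split()
    try:
        precursor_mh = float(header[0])
        charge = int(float(header[1]))
    except (IndexError, ValueError):
        raise ValueError(f"{source_file}: malformed header at line 1: {lines[0]!r}") from None
    mzs, intens = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split()
        try:
            mzs.append(float(fields[0]))
            intens.append(float(fields[1]))
        except (IndexError, ValueError):
            raise ValueError(f"{source_file}: malformed peak at line {lineno}: {ln!r}") from None
    if not mzs:
        raise ValueError(f"{source_file}: no peaks")
    return Spectrum.from_peaks(precursor_mh, charge, mzs, intens, source_file)


def load_dta_directory(directory: str | Path) -> list[Spectrum]:
    """Load every .dta file (case-insensitive) under a directory.

    Recurses one level into subdirectories; results are sorted by relative
    path for run-to-run determinism.
    """
    directory = Path(directory)
    paths: list[Path] = []
    for entry in sorted(directory.iterdir()):
        if entry.is_file() and entry.suffix.lower() == ".dta":
            paths.append(entry)
        elif entry.is_dir():
            for sub in sorted(entry.iterdir()):
                if sub.is_file() and sub.suffix.lower() == ".dta":
                    paths.append(sub)
    spectra = []
    for path in paths:
        rel = os.path.relpath(path, directory)
        spectra.append(parse_dta(path.read_text(), source_file=rel))
    return spectra


def parse_mgf(content: str, source_file: str = "<memory>") -> list[Spectrum]:
    """Minimal MGF reader (BEGIN IONS/END IONS, PEPMASS, CHARGE, TITLE).

    PEPMASS is interpreted as the precursor m/z; the stored ``precursor_mh``
    is converted to the singly protonated convention used by DTA files.
    """
    spectra: list[Spectrum] = []
    in_block = False
    pepmass = charge = None
    title = ""
    mzs: list[float] = []
    intens: list[float] = []
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, pepmass, charge, title, mzs, intens = True, None, 1, "", [], []
        elif line == "END IONS":
            if pepmass is None:
                raise ValueError(f"{source_file}: spectrum ending at line {lineno} has no PEPMASS")
            if not mzs:
                raise ValueError(f"{source_file}: spectrum ending at line {lineno} has no peaks")
            mh = pepmass * charge - (charge - 1) * PROTON
            spectra.append(Spectrum.from_peaks(mh, charge, mzs, intens,
                                               title or source_file))
            in_block = False
        elif in_block:
            if line.startswith("PEPMASS="):
                pepmass = float(line.split("=", 1)[1].split()[0])
            elif line.startswith("CHARGE="):
                charge = int(line.split("=", 1)[1].rstrip("+-"))
            elif line.startswith("TITLE="):
                title = line.split("=", 1)[1]
            elif "=" not in line:
                fields = line.split()
                mzs.append(float(fields[0]))
                intens.append(float(fields[1]))
    return spectra


def noise_filter(spectrum: Spectrum, fraction: float = 0.005) -> Spectrum:
    """Drop peaks below ``fraction`` of the total intensity sum.

    The threshold is computed once on the pre-filter sum (one-pass
    contract); peak order is preserved.  A spectrum losing all of its peaks
    is rejected as unscorable.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("noise fraction must be in [0, 1)")
    threshold = fraction * float(spectrum.intensity.sum())
    keep = spectrum.intensity >= threshold
    if not keep.any():
        raise ValueError(f"{spectrum.source_file}: noise filter removed every peak")
    return Spectrum(
        spectrum.source_file,
        spectrum.precursor_mh,
        spectrum.parent_charge,
        spectrum.mz[keep].copy(),
        spectrum.intensity[keep].copy(),
    )


def peak_density(spectrum: Spectrum) -> float:
    """Peaks per Dalton: peak count over the observed m/z span."""
    if spectrum.n_peaks < 2:
        raise ValueError("peak density needs at least 2 peaks")
    span = float(spectrum.mz.max() - spectrum.mz.min())
    if span <= 0:
        raise ValueError("degenerate m/z range")
    return spectrum.n_peaks / span


def top_intense_peaks(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray, int]:
    """Return the top 4N peaks by intensity, plus N.

    N is the estimated sequence length: round(neutral_mass / 114), floored
    at 1.  If fewer than 4N peaks exist, all peaks are returned.  Ties in
    intensity are broken by ascending m/z (already the storage order).
    """
    if spectrum.neutral_mass <= 0:
        raise ValueError("non-positive neutral mass")
    n_est = max(1, int(math.floor(spectrum.neutral_mass / AVERAGE_RESIDUE_MASS + 0.5)))
    count = min(4 * n_est, spectrum.n_peaks)
    return spectrum.mz[:count], spectrum.intensity[:count], n_est
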