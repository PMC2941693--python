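"""Candidate selection: precursor-mass window, y-ion hits, preliminary score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import DEFAULT_TABLE, AminoAcidTable, IonConfig, generate_ion_series
from .database import Peptide, PeptideIndex, query_by_mass
from .lod import FragmentMatch
from .spectra import Spectrum, top_intense_peaks

__all__ = [
    "Candidate",
    "count_y_matches",
    "preliminary_score",
    "select_candidates",
]


@dataclass
class Candidate:
    """A peptide retained for a spectrum, with scores filled in as the
    pipeline progresses."""

    peptide: Peptide
    spectrum_ref: str
    y_hits: int
    preliminary_score: float
    matches: list[FragmentMatch] = field(default_factory=list)
    peptide_lod: float = 0.0
    z_score: float | None = None
    intensity_z: float | None = None

    @property
    def combined_z(self) -> float | None:
        """Metric-4 Z plus the intensity-prediction Z (the complex metric)."""
        if self.z_score is None:
            return None
        return self.z_score + (self.intensity_z or 0.0)


def count_y_matches(spectrum: Spectrum, peptide: Peptide, tolerance: float) -> int:
    """Number of pre-computed y1+ ions with at least one peak within
    +/- ``tolerance``; each y ion counts at most once."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not peptide.y_series or spectrum.n_peaks == 0:
        return 0
    y = np.asarray(peptide.y_series)
    hits = np.abs(spectrum.mz[None, :] - y[:, None]) <= tolerance
    return int(hits.any(axis=1).sum())


def preliminary_score(
    spectrum: Spectrum,
    peptide: Peptide,
    tolerance: float,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """Proportion of top-4N peak intensity matched to y1+/b1+/iminium ions
    (plus y2+ when the parent charge is 2 or higher).

    A peak may satisfy several ions but its intensity enters the numerator
    only once.
    """
    mz, intensity, _ = top_intense_peaks(spectrum)
    total = float(intensity.sum())
    if total <= 0:
        return 0.0
    ions = generate_ion_series(
        peptide.sequence,
        peptide.applied_mods,
        IonConfig.preliminary(),
        parent_charge=spectrum.parent_charge,
        table=table,
    )
    ion_mz = np.array([ion.mz for ion in ions])
    matched = (np.abs(mz[None, :] - ion_mz[:, None]) <= tolerance).any(axis=0)
    return float(intensity[matched].sum()) / total


def select_candidates(
    spectrum: Spectrum,
    index: PeptideIndex,
    precursor_tol: float = 2.5,
    fragment_tol: float = 0.5,
    min_y_hits: int = 2,
    min_prelim: float = 0.05,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[Candidate]:
    """Three-stage selection: mass window, then y-hit count, then
    preliminary score.

    The result is sorted by (mass, sequence) so it does not depend on the
    on-disk order of spectra or peaks.
    """
    out: list[Candidate] = []
    for peptide in query_by_mass(index, spectrum.neutral_mass, precursor_tol):
        y_hits = count_y_matches(spectrum, peptide, fragment_tol)
        if y_hits < min_y_hits:
            continue
        prelim = preliminary_score(spectrum, peptide, fragment_tol, table)
        if prelim < min_prelim:
            continue
        out.append(
            Candidate(
                peptide=peptide,
                spectrum_ref=spectrum.source_file,
                y_hits=y_hits,
                preliminary_score=prelim,
            )
        )
    out.sort(key=lambda c: (c.peptide.neutral_mass, c.peptide.sequence, c.peptide.protein_id))
    return out
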