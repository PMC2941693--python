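"""Empirical model building for metrics 2-4.

From a set of assignments this module derives the per-charge-class
mass-binned match-proportion tables, their normalized distributions, and
the per-bin mass-error probability density functions.  Table building is a
pure function of the assignment set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import DEFAULT_TABLE, AminoAcidTable, IonConfig
from .database import Peptide
from .lod import (
    ERROR_PDF_BIN,
    MATCH_PROPORTION_BIN,
    SIGMA_FLOOR,
    FragmentMatch,
    MatchProbabilityModel,
    charge_class,
    mass_bin,
    match_fragments,
)
from .spectra import Spectrum

__all__ = [
    "Assignment",
    "fragment_observations",
    "build_match_proportion_table",
    "normalize_distribution",
    "fit_error_pdf",
    "build_model",
]

log = logging.getLogger(__name__)

#: Default Z threshold selecting the high-confidence training assignments.
Z_TRAIN_DEFAULT = 6.0
#: Minimum error count for a mass-error PDF bin to be fitted.
MIN_ERRORS_PER_BIN = 5


@dataclass
class Assignment:
    """One scored spectrum/peptide pairing used for model building."""

    spectrum_id: str
    peptide: Peptide
    parent_charge: int
    matches: list[FragmentMatch]
    peptide_lod: float
    z_score: float | None = None


def fragment_observations(
    spectrum: Spectrum,
    peptide: Peptide,
    tolerance: float,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[tuple[float, bool]]:
    """(expected m/z, matched) for every base y1+/b1+ ion of a peptide.

    The denominator population for the match-proportion tables: all
    theoretical base ions, flagged matched when the one-to-one fragment
    matcher pairs them with an observed peak.
    """
    config = IonConfig(ion_types=("y", "b"), include_y2=False)
    matches = match_fragments(spectrum, peptide, tolerance, config, 1, table)
    matched_keys = {(m.ion.ion_type, m.ion.index) for m in matches}
    from .chem import generate_ion_series

    ions = generate_ion_series(peptide.sequence, peptide.applied_mods, config, 1, table)
    return [(ion.mz, (ion.ion_type, ion.index) in matched_keys) for ion in ions]


def build_match_proportion_table(
    observations: Iterable[tuple[int, float, bool]],
    bin_width: float = MATCH_PROPORTION_BIN,
) -> dict[str, dict[float, float]]:
    """Per-charge-class {bin upper edge -> matched/total proportion}.

    ``observations`` yields (parent_charge, expected m/z, matched).  Only
    the 1+ and 2+ classes are tabulated; 3+ parents are served at lookup
    time by the constant average of all 1+ and 2+ proportions.  Empty bins
    are simply absent (nearest-bin fallback happens at lookup).
    """
    counts: dict[str, dict[float, list[int]]] = {}
    n = 0
    for parent_charge, expected_mz, matched in observations:
        n += 1
        cls = charge_class(parent_charge)
        if cls == "3plus":
            continue
        edge = mass_bin(expected_mz, bin_width)
        bucket = counts.setdefault(cls, {}).setdefault(edge, [0, 0])
        bucket[0] += int(matched)
        bucket[1] += 1
    if n == 0:
        raise ValueError("no fragment observations supplied")
    return {
        cls: {edge: m / t for edge, (m, t) in sorted(bins.items())}
        for cls, bins in counts.items()
    }


def normalize_distribution(table: Mapping[float, float]) -> dict[float, float]:
    """Divide each bin value by the table sum so the bins sum to one."""
    total = float(sum(table.values()))
    if total <= 0:
        raise ValueError("cannot normalize an all-zero table")
    return {edge: value / total for edge, value in table.items()}


def fit_error_pdf(
    errors: Iterable[tuple[float, float]],
    bin_width: float = ERROR_PDF_BIN,
    min_count: int = MIN_ERRORS_PER_BIN,
    sigma_floor: float = SIGMA_FLOOR,
) -> dict[float, tuple[float, float]]:
    """Per-bin (mu, sigma) of signed mass errors.

    ``errors`` yields (expected m/z, signed error).  Bins with fewer than
    ``min_count`` errors are left missing and served by nearest-bin
    fallback at lookup; sigma is floored.
    """
    binned: dict[float, list[float]] = {}
    for expected_mz, err in errors:
        binned.setdefault(mass_bin(expected_mz, bin_width), []).append(err)
    pdfs: dict[float, tuple[float, float]] = {}
    for edge in sorted(binned):
        values = np.asarray(binned[edge])
        if values.size < min_count:
            log.debug("error-PDF bin %s has %d < %d errors; skipping", edge, values.size, min_count)
            continue
        mu = float(values.mean())
        sigma = max(float(values.std(ddof=1)), sigma_floor)
        pdfs[edge] = (mu, sigma)
    if not pdfs:
        raise ValueError("no error-PDF bin reached the minimum error count")
    return pdfs


def build_model(
    correct: Sequence[tuple[Assignment, Spectrum]],
    random: Sequence[tuple[Assignment, Spectrum]],
    fragment_tol: float = 0.5,
    z_train: float = Z_TRAIN_DEFAULT,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> MatchProbabilityModel:
    """Build a full probability model from scored runs.

    ``correct`` assignments are filtered to Z > ``z_train`` (high
    confidence); ``random`` assignments are expected to come from a decoy
    run with no Z requirement.  Error PDFs are fitted from the matched
    fragments of the high-confidence set.
    """

    def observations(pairs, require_z):
        for assignment, spectrum in pairs:
            if require_z and (assignment.z_score is None or assignment.z_score <= z_train):
                continue
            for expected_mz, matched in fragment_observations(
                spectrum, assignment.peptide, fragment_tol, table
            ):
                yield assignment.parent_charge, expected_mz, matched

    correct_table = build_match_proportion_table(observations(correct, True))
    random_table = build_match_proportion_table(observations(random, False))

    def matched_errors(pairs):
        for assignment, _spectrum in pairs:
            if assignment.z_score is None or assignment.z_score <= z_train:
                continue
            for m in assignment.matches:
                yield m.ion.mz, m.mass_error

    error_pdfs = fit_error_pdf(matched_errors(correct))
    return MatchProbabilityModel(
        correct_table=correct_table,
        random_table=random_table,
        error_pdfs=error_pdfs,
    )
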