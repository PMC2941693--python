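"""End-to-end scoring: candidates, fragment LODs, decoy Z scores, and the
optional intensity-network term."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .candidates import Candidate, select_candidates
from .chem import DEFAULT_TABLE, AminoAcidTable, IonConfig
from .database import Peptide, PeptideIndex, query_by_mass
from .lod import (
    MatchProbabilityModel,
    fragment_lod,
    match_fragments,
    peptide_lod,
    z_score,
)
from .network import encode_features, intensity_z_score
from .spectra import Spectrum, noise_filter, peak_density

__all__ = ["ScoringParams", "score_spectrum", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring pipeline.

    ``min_prelim_score`` defaults to 0.05; 0.30 can suit MALDI data.  The
    decoy mass window is widened symmetrically (doubling, up to
    ``decoy_max_tol_da``) until ``min_decoys`` decoy candidates are found;
    otherwise the Z score is reported missing.  ``z_threshold`` is the
    default acceptance cutoff of 3.29.
    """

    metric: str = "1"
    precursor_tol_da: float = 2.5
    fragment_tol_da: float = 0.5
    min_y_hits: int = 2
    min_prelim_score: float = 0.05
    noise_fraction: float = 0.005
    min_decoys: int = 20
    decoy_max_tol_da: float = 10.0
    z_threshold: float = 3.29
    include_iminium_in_probability: bool = False
    apply_noise_filter: bool = True


def _decoy_lods(
    spectrum: Spectrum,
    decoy_index: PeptideIndex,
    params: ScoringParams,
    density: float,
    model: MatchProbabilityModel | None,
    table: AminoAcidTable,
) -> list[float]:
    """Peptide LODs of decoy candidates in a (possibly widened) window."""
    config = IonConfig.probability(params.include_iminium_in_probability)
    tol = params.precursor_tol_da
    decoys: list[Peptide] = []
    while True:
        decoys = query_by_mass(decoy_index, spectrum.neutral_mass, tol)
        if len(decoys) >= params.min_decoys or tol >= params.decoy_max_tol_da:
            break
        tol = min(tol * 2.0, params.decoy_max_tol_da)
    lods = []
    for decoy in decoys:
        matches = match_fragments(
            spectrum, decoy, params.fragment_tol_da, config,
            spectrum.parent_charge, table,
        )
        for m in matches:
            m.fragment_lod = fragment_lod(
                m, params.metric, density, model, spectrum.parent_charge
            )
        lods.append(peptide_lod(matches))
    return lods


def score_spectrum(
    spectrum: Spectrum,
    target_index: PeptideIndex,
    decoy_index: PeptideIndex | None = None,
    params: ScoringParams = ScoringParams(),
    model: MatchProbabilityModel | None = None,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[Candidate]:
    """Score every surviving candidate for one spectrum.

    Returns candidates sorted best-first by (combined) Z score, then by
    peptide LOD.  Metrics 2-4 and 'nn4' need a probability model; 'nn4'
    additionally needs ``model.network`` and adds the intensity Z score to
    the metric-4 Z.
    """
    if params.metric != "1" and model is None:
        raise ValueError(f"metric {params.metric} requires a probability model")
    if params.metric == "nn4" and (model is None or model.network is None):
        raise ValueError("metric nn4 requires a trained intensity network")

    if params.apply_noise_filter and params.noise_fraction > 0:
        spectrum = noise_filter(spectrum, params.noise_fraction)
    if spectrum.n_peaks < 2 or spectrum.mz.max() == spectrum.mz.min():
        log.debug("%s: too few distinct peaks to score", spectrum.source_file)
        return []
    density = peak_density(spectrum)

    candidates = select_candidates(
        spectrum,
        target_index,
        precursor_tol=params.precursor_tol_da,
        fragment_tol=params.fragment_tol_da,
        min_y_hits=params.min_y_hits,
        min_prelim=params.min_prelim_score,
        table=table,
    )
    if not candidates:
        return []

    config = IonConfig.probability(params.include_iminium_in_probability)
    for cand in candidates:
        cand.matches = match_fragments(
            spectrum, cand.peptide, params.fragment_tol_da, config,
            spectrum.parent_charge, table,
        )
        for m in cand.matches:
            m.fragment_lod = fragment_lod(
                m, params.metric, density, model, spectrum.parent_charge
            )
        cand.peptide_lod = peptide_lod(cand.matches)

    if decoy_index is not None:
        decoy_lods = _decoy_lods(spectrum, decoy_index, params, density, model, table)
        for cand in candidates:
            cand.z_score = z_score(cand.peptide_lod, decoy_lods, params.min_decoys)

    if params.metric == "nn4":
        for cand in candidates:
            cand.intensity_z = _network_z(cand, spectrum.parent_charge, model, table)

    candidates.sort(
        key=lambda c: (
            -(c.combined_z if c.combined_z is not None else float("-inf")),
            -c.peptide_lod,
            c.peptide.sequence,
        )
    )
    return candidates


def _network_z(
    candidate: Candidate,
    parent_charge: int,
    model: MatchProbabilityModel,
    table: AminoAcidTable,
) -> float:
    matches = candidate.matches
    if len(matches) < 3:
        return 0.0
    feats = np.stack([
        encode_features(m.ion, candidate.peptide.sequence, parent_charge, table)
        for m in matches
    ])
    predicted_log = model.network.predict(feats)
    predicted = np.exp(predicted_log)
    observed = np.array([m.observed_intensity for m in matches])
    return float(intensity_z_score(observed, predicted))


def run_pipeline(
    spectra,
    target_index: PeptideIndex,
    decoy_index: PeptideIndex | None = None,
    params: ScoringParams = ScoringParams(),
    model: MatchProbabilityModel | None = None,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> dict[str, list[Candidate]]:
    """Score a batch of spectra; returns {spectrum source file: candidates}."""
    results: dict[str, list[Candidate]] = {}
    for i, spectrum in enumerate(spectra):
        try:
            results[spectrum.source_file] = score_spectrum(
                spectrum, target_index, decoy_index, params, model, table
            )
        except ValueError as exc:
            log.warning("%s: skipped (%s)", spectrum.source_file, exc)
            results[spectrum.source_file] = []
        if (i + 1) % 1000 == 0:
            log.info("scored %d spectra", i + 1)
    return results
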