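"""Probability scoring: fragment matching, the four LOD metrics, and Z scores.

A fragment LOD is the natural log of the odds that a theoretical-ion /
observed-peak pairing is correct rather than random; the peptide LOD is the
sum of its fragment LODs.  Z scores calibrate peptide LODs against decoy
candidates drawn from a reversed database in the same precursor window.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import DEFAULT_TABLE, AminoAcidTable, IonConfig, TheoreticalIon, generate_ion_series
from .database import Peptide
from .spectra import Spectrum

__all__ = [
    "FragmentMatch",
    "MatchProbabilityModel",
    "match_fragments",
    "random_match_probability",
    "fragment_lod_metric1",
    "fragment_lod_metric2",
    "fragment_lod_metric3",
    "fragment_lod_metric4",
    "fragment_lod",
    "peptide_lod",
    "z_score",
    "mass_bin",
]

log = logging.getLogger(__name__)

#: Fixed probability of a correct fragment match under metric 1.
P_CORRECT_FIXED = 0.5
#: Floors keeping LODs finite (exact matches, empty bins, tight nulls).
P_RANDOM_FLOOR = 1e-4
ERROR_FLOOR = 0.005
SIGMA_FLOOR = 0.01
SD_FLOOR = 1e-6
NORM_FLOOR = 1e-9

MATCH_PROPORTION_BIN = 200.0
ERROR_PDF_BIN = 100.0


@dataclass
class FragmentMatch:
    """One theoretical-ion <-> observed-peak pairing.

    ``mass_error`` is signed, observed minus expected (Da).
    """

    ion: TheoreticalIon
    observed_mz: float
    observed_intensity: float
    mass_error: float
    fragment_lod: float = 0.0


def mass_bin(mass: float, width: float) -> float:
    """Upper edge of the bin holding ``mass``.

    Bins are lower-exclusive / upper-inclusive and labeled by their upper
    edge; the first bin contains everything <= ``width``.
    """
    return width * max(1, math.ceil(mass / width))


def charge_class(parent_charge: int) -> str:
    """Model charge class: '1', '2', or '3plus'."""
    if parent_charge <= 1:
        return "1"
    if parent_charge == 2:
        return "2"
    return "3plus"


def _lookup_nearest(table: Mapping[float, float], bin_edge: float) -> float:
    """Value at ``bin_edge``, falling back to the nearest populated bin."""
    if bin_edge in table:
        return table[bin_edge]
    if not table:
        raise ValueError("empty model table")
    nearest = min(table, key=lambda edge: (abs(edge - bin_edge), edge))
    log.debug("bin %s missing; falling back to nearest populated bin %s", bin_edge, nearest)
    return table[nearest]


@dataclass
class MatchProbabilityModel:
    """Empirical artefacts driving metrics 2-4.

    ``correct_table``/``random_table`` map a charge class ('1' or '2') to a
    {bin upper edge -> match proportion} table; 3+ parents use the constant
    average of all 1+ and 2+ proportions.  ``correct_norm``/``random_norm``
    are the per-class distributions renormalized to sum to one (metric 3).
    ``error_pdfs`` maps 100 Da bins to (mu, sigma) of the signed mass error
    (metric 4).
    """

    p_correct_fixed: float = P_CORRECT_FIXED
    correct_table: dict[str, dict[float, float]] = field(default_factory=dict)
    random_table: dict[str, dict[float, float]] = field(default_factory=dict)
    error_pdfs: dict[float, tuple[float, float]] = field(default_factory=dict)
    network: "object | None" = None  # IntensityNetwork, attached by train-nn

    # -- derived ------------------------------------------------------------
    def _normalize(self, table: Mapping[float, float]) -> dict[float, float]:
        total = sum(table.values())
        if total <= 0:
            raise ValueError("cannot normalize an all-zero table")
        return {k: v / total for k, v in table.items()}

    def norm_tables(self, cls: str) -> tuple[dict[float, float], dict[float, float]]:
        correct = self._class_table(self.correct_table, cls)
        random = self._class_table(self.random_table, cls)
        return self._normalize(correct), self._normalize(random)

    def _class_table(self, tables: dict[str, dict[float, float]], cls: str) -> dict[float, float]:
        if cls in tables:
            return tables[cls]
        if cls == "3plus":
            # element-wise mean of the 1+ and 2+ tables over their union
            merged: dict[float, list[float]] = {}
            for sub in ("1", "2"):
                for edge, val in tables.get(sub, {}).items():
                    merged.setdefault(edge, []).append(val)
            if merged:
                return {edge: sum(vals) / len(vals) for edge, vals in merged.items()}
        available = next(iter(tables.values()), None)
        if available is None:
            raise ValueError(f"model has no table for charge class {cls!r}")
        return available

    def average_proportion(self, tables: dict[str, dict[float, float]]) -> float:
        """Average of all 1+ and 2+ proportions (the 3+ constant)."""
        values = [v for sub in ("1", "2") for v in tables.get(sub, {}).values()]
        if not values:
            raise ValueError("model has no 1+/2+ proportions")
        return sum(values) / len(values)

    def p_correct(self, expected_mz: float, parent_charge: int) -> float:
        cls = charge_class(parent_charge)
        if cls == "3plus":
            return self.average_proportion(self.correct_table)
        table = self._class_table(self.correct_table, cls)
        return _lookup_nearest(table, mass_bin(expected_mz, MATCH_PROPORTION_BIN))

    def error_pdf(self, expected_mz: float) -> tuple[float, float]:
        mu, sigma = _lookup_nearest_pair(self.error_pdfs, mass_bin(expected_mz, ERROR_PDF_BIN))
        return mu, max(sigma, SIGMA_FLOOR)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "format": "psmlod-model",
            "version": 1,
            "p_correct_fixed": self.p_correct_fixed,
            "correct_table": {c: {str(k): v for k, v in t.items()}
                              for c, t in self.correct_table.items()},
            "random_table": {c: {str(k): v for k, v in t.items()}
                             for c, t in self.random_table.items()},
            "error_pdfs": {str(k): list(v) for k, v in self.error_pdfs.items()},
        }
        if self.network is not None:
            out["network"] = self.network.to_dict()
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "MatchProbabilityModel":
        if obj.get("format") != "psmlod-model":
            raise ValueError("not a scoring-model document")
        network = None
        if obj.get("network") is not None:
            from .network import IntensityNetwork

            network = IntensityNetwork.from_dict(obj["network"])
        return cls(
            p_correct_fixed=obj.get("p_correct_fixed", P_CORRECT_FIXED),
            correct_table={c: {float(k): v for k, v in t.items()}
                           for c, t in obj.get("correct_table", {}).items()},
            random_table={c: {float(k): v for k, v in t.items()}
                          for c, t in obj.get("random_table", {}).items()},
            error_pdfs={float(k): (v[0], v[1])
                        for k, v in obj.get("error_pdfs", {}).items()},
            network=network,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MatchProbabilityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _lookup_nearest_pair(
    table: Mapping[float, tuple[float, float]], bin_edge: float
) -> tuple[float, float]:
    if bin_edge in table:
        return table[bin_edge]
    if not table:
        raise ValueError("empty error-PDF table")
    nearest = min(table, key=lambda edge: (abs(edge - bin_edge), edge))
    return table[nearest]


# ---------------------------------------------------------------------------
# fragment matching

def match_fragments(
    spectrum: Spectrum,
    peptide: Peptide,
    tolerance: float,
    config: IonConfig | None = None,
    parent_charge: int | None = None,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[FragmentMatch]:
    """One-to-one greedy assignment of theoretical ions to observed peaks.

    Candidate pairs within ``tolerance`` are sorted by absolute error (ties
    broken by lower theoretical m/z, then lower observed m/z) and claimed
    greedily; each ion and each peak is used at most once.  The returned
    matches are sorted by theoretical m/z.
    """
    if config is None:
        config = IonConfig.probability()
    if parent_charge is None:
        parent_charge = spectrum.parent_charge
    ions = generate_ion_series(
        peptide.sequence, peptide.applied_mods, config, parent_charge, table
    )
    if spectrum.n_peaks == 0 or not ions:
        return []
    ion_mz = np.array([ion.mz for ion in ions])
    diff = spectrum.mz[None, :] - ion_mz[:, None]
    ion_idx, peak_idx = np.nonzero(np.abs(diff) <= tolerance)
    # |error| is quantized to 1e-9 Th for ordering so that exact ties (up to
    # float noise) resolve by the documented rule: lower theoretical m/z wins
    order = sorted(
        range(ion_idx.size),
        key=lambda k: (
            round(abs(diff[ion_idx[k], peak_idx[k]]), 9),
            ion_mz[ion_idx[k]],
            spectrum.mz[peak_idx[k]],
        ),
    )
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[FragmentMatch] = []
    for k in order:
        i, p = int(ion_idx[k]), int(peak_idx[k])
        if i in used_ions or p in used_peaks:
            continue
        used_ions.add(i)
        used_peaks.add(p)
        matches.append(
            FragmentMatch(
                ion=ions[i],
                observed_mz=float(spectrum.mz[p]),
                observed_intensity=float(spectrum.intensity[p]),
                mass_error=float(diff[i, p]),
            )
        )
    matches.sort(key=lambda m: m.ion.mz)
    return matches


# ---------------------------------------------------------------------------
# the four metrics

def random_match_probability(
    mass_error: float,
    density: float,
    p_floor: float = P_RANDOM_FLOOR,
    error_floor: float = ERROR_FLOOR,
) -> float:
    """Probability that a uniformly placed peak lands within +/-|error|.

    p = 2 * |error| * density, clamped to [p_floor, 1].  The error floor
    keeps exact matches from producing infinite LODs.
    """
    if density <= 0:
        raise ValueError("peak density must be > 0")
    err = max(abs(mass_error), error_floor)
    return min(1.0, max(p_floor, 2.0 * err * density))


def fragment_lod_metric1(
    match: FragmentMatch, density: float, p_correct: float = P_CORRECT_FIXED
) -> float:
    """ln(p_correct / p_random) with the fixed correct probability 0.5."""
    return math.log(p_correct / random_match_probability(match.mass_error, density))


def fragment_lod_metric2(
    match: FragmentMatch,
    model: MatchProbabilityModel,
    density: float,
    parent_charge: int = 1,
) -> float:
    """Metric 1 with the fixed correct probability replaced by the
    empirical mass-binned proportion for this fragment."""
    p_correct = model.p_correct(match.ion.mz, parent_charge)
    return math.log(p_correct / random_match_probability(match.mass_error, density))


def fragment_lod_metric3(
    match: FragmentMatch,
    model: MatchProbabilityModel,
    parent_charge: int = 1,
) -> float:
    """ln of the ratio of normalized correct and random bin probabilities."""
    cls = charge_class(parent_charge)
    correct_norm, random_norm = model.norm_tables(cls)
    edge = mass_bin(match.ion.mz, MATCH_PROPORTION_BIN)
    p_c = max(_lookup_nearest(correct_norm, edge), NORM_FLOOR)
    p_r = _lookup_nearest(random_norm, edge)
    if p_r <= 0:
        log.warning("zero random-norm bin at %s Da; flooring", edge)
        p_r = NORM_FLOOR
    return math.log(p_c / p_r)


def fragment_lod_metric4(
    match: FragmentMatch,
    model: MatchProbabilityModel,
    parent_charge: int = 1,
) -> float:
    """Metric 3 weighted by a max-normalized Gaussian on the mass error.

    w = exp(-(error - mu)^2 / (2 sigma^2)) with the (mu, sigma) of the
    fragment's 100 Da mass bin; LOD = metric3 + ln(w).
    """
    mu, sigma = model.error_pdf(match.ion.mz)
    w = math.exp(-((match.mass_error - mu) ** 2) / (2.0 * sigma ** 2))
    return fragment_lod_metric3(match, model, parent_charge) + math.log(w)


def fragment_lod(
    match: FragmentMatch,
    metric: str,
    density: float,
    model: MatchProbabilityModel | None = None,
    parent_charge: int = 1,
) -> float:
    """Dispatch on the metric id ('1', '2', '3', '4', 'nn4').

    The neural-network metric scores fragments exactly as metric 4; its
    intensity term enters at the peptide level as an added Z score.
    """
    if metric == "1":
        return fragment_lod_metric1(match, density)
    if model is None:
        raise ValueError(f"metric {metric} requires a probability model")
    if metric == "2":
        return fragment_lod_metric2(match, model, density, parent_charge)
    if metric == "3":
        return fragment_lod_metric3(match, model, parent_charge)
    if metric in ("4", "nn4"):
        return fragment_lod_metric4(match, model, parent_charge)
    raise ValueError(f"unknown metric {metric!r}")


def peptide_lod(matches: Sequence[FragmentMatch]) -> float:
    """Sum of the fragment LODs; 0 for an empty match list."""
    return float(sum(m.fragment_lod for m in matches))


def z_score(
    candidate_lod: float,
    decoy_lods: Sequence[float],
    min_decoys: int = 20,
    sd_floor: float = SD_FLOOR,
) -> float | None:
    """Standard-score of a candidate LOD against decoy LODs.

    Uses the sample (n-1) standard deviation; returns ``None`` when fewer
    than ``min_decoys`` decoy scores are available.
    """
    if len(decoy_lods) < max(2, min_decoys):
        return None
    arr = np.asarray(decoy_lods, dtype=float)
    sd = float(arr.std(ddof=1))
    if sd < sd_floor:
        log.warning("decoy LOD spread below floor (%.2g); flooring", sd)
        sd = sd_floor
    return float((candidate_lod - arr.mean()) / sd)
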