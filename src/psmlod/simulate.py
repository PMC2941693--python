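"""Synthetic proteomes and spectra with known ground truth.

Every stage of the scoring pipeline can be exercised offline: fragment
inclusion follows configurable per-mass-bin probabilities, mass errors are
Gaussian with a mass-dependent drift, intensities come from a deterministic
model of the fragment feature vector, and uniform noise peaks are added on
top.  All randomness derives from per-spectrum streams seeded by
(seed, spectrum ordinal), so generation is byte-reproducible and
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .chem import DEFAULT_TABLE, AminoAcidTable, IonConfig, PROTON, TheoreticalIon, generate_ion_series
from .database import Peptide, PeptideIndex, build_index
from .lod import mass_bin
from .network import encode_features
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "default_intensity_model",
    "generate_database",
    "simulate_spectrum",
    "simulate_spectra",
    "write_spectra",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def default_intensity_model(
    ion: TheoreticalIon,
    peptide_sequence: str,
    parent_charge: int,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """Deterministic log-intensity: linear in length ratio, basic-residue
    ratio, flanking-residue codes, plus an ion-type offset.

    Chosen so the intensity network has recoverable signal.
    """
    f = encode_features(ion, peptide_sequence, parent_charge, table)
    offsets = {2: 0.8, 4: 0.3, 3: -0.6, 1: -0.3, 0: 0.0}  # y, b, a, iminium, precursor
    return 1.0 + 2.5 * f[4] + 1.5 * f[5] + 0.5 * f[6] - 0.4 * f[7] + offsets[int(f[0])]


INTENSITY_MODELS: dict[str, Callable] = {"default": default_intensity_model}


@dataclass
class SimulationConfig:
    """Knobs for the synthetic proteome and spectrum generator."""

    seed: int = 0
    n_proteins: int = 10
    protein_length_range: tuple[int, int] = (50, 120)
    #: probability that a theoretical y/b ion appears, keyed by the upper
    #: edge of its 200 Da mass bin; missing bins use ``default_match_prob``
    bin_match_probs: Mapping[float, float] = field(default_factory=dict)
    default_match_prob: float = 1.0
    #: mass-error model: error ~ Normal(intercept + slope * m, error_sigma)
    drift_slope: float = 0.0
    drift_intercept: float = 0.0
    error_sigma: float = 0.0
    intensity_model: str = "default"
    n_noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    noise_intensity_range: tuple[float, float] = (0.5, 20.0)
    #: sampling weights for the parent charge states 1/2/3
    charge_distribution: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})

    def __post_init__(self) -> None:
        for p in self.bin_match_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("bin match probabilities must be in [0, 1]")
        if not 0.0 <= self.default_match_prob <= 1.0:
            raise ValueError("default_match_prob must be in [0, 1]")


@dataclass
class SimulatedSpectrum:
    """A generated spectrum plus its ground truth."""

    spectrum: Spectrum
    peptide: Peptide
    parent_charge: int
    #: (ion label, expected m/z, included flag) for every candidate ion
    ion_truth: list[tuple[str, float, bool]]


def generate_database(
    config: SimulationConfig,
    table: AminoAcidTable = DEFAULT_TABLE,
    **index_kwargs,
) -> tuple[str, PeptideIndex]:
    """Random proteome FASTA text plus its digested index (no mods)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    lines = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(ALPHABET), size=length))
        lines.append(f">sim{i:04d}")
        lines.append(seq)
    fasta = "\n".join(lines) + "\n"
    index_kwargs.setdefault("mod_specs", ())
    index = build_index(fasta, table=table, **index_kwargs)
    return fasta, index


def _inclusion_probability(config: SimulationConfig, mz: float) -> float:
    if not config.bin_match_probs:
        return config.default_match_prob
    edge = mass_bin(mz, 200.0)
    return config.bin_match_probs.get(edge, config.default_match_prob)


def simulate_spectrum(
    config: SimulationConfig,
    peptide: Peptide,
    ordinal: int,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> SimulatedSpectrum:
    """Generate one spectrum from a peptide.

    Theoretical y1+/b1+ ions are included with their bin probability,
    displaced by the drift+Gaussian error model, and given intensities from
    the configured deterministic model normalized so the largest signal
    peak is 100.  Uniform noise peaks are appended afterwards.
    """
    rng = np.random.default_rng([config.seed, ordinal])
    charges = sorted(config.charge_distribution)
    weights = np.array([config.charge_distribution[c] for c in charges], dtype=float)
    charge = int(rng.choice(charges, p=weights / weights.sum()))

    ion_config = IonConfig(ion_types=("y", "b"), include_y2=False)
    ions = generate_ion_series(
        peptide.sequence, peptide.applied_mods, ion_config, charge, table
    )
    model = INTENSITY_MODELS[config.intensity_model]

    truth: list[tuple[str, float, bool]] = []
    mzs: list[float] = []
    intens: list[float] = []
    for ion in ions:
        include = bool(rng.random() < _inclusion_probability(config, ion.mz))
        truth.append((ion.label, ion.mz, include))
        if not include:
            continue
        mu = config.drift_intercept + config.drift_slope * ion.mz
        observed = ion.mz + mu + (rng.normal(0.0, config.error_sigma)
                                  if config.error_sigma > 0 else 0.0)
        mzs.append(observed)
        intens.append(math.exp(model(ion, peptide.sequence, charge, table)))

    if intens:
        scale = 100.0 / max(intens)
        intens = [v * scale for v in intens]

    for _ in range(config.n_noise_peaks):
        mzs.append(float(rng.uniform(*config.noise_mz_range)))
        intens.append(float(rng.uniform(*config.noise_intensity_range)))

    if not mzs:  # every ion dropped and no noise requested: keep one marker peak
        mzs, intens = [config.noise_mz_range[0]], [1.0]

    spectrum = Spectrum.from_peaks(
        precursor_mh=peptide.neutral_mass + PROTON,
        parent_charge=charge,
        mz=mzs,
        intensity=intens,
        source_file=f"sim_{ordinal:06d}.dta",
    )
    return SimulatedSpectrum(spectrum, peptide, charge, truth)


def simulate_spectra(
    config: SimulationConfig,
    peptides: Sequence[Peptide],
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[SimulatedSpectrum]:
    if not peptides:
        raise ValueError("no peptides to simulate")
    return [
        simulate_spectrum(config, peptide, ordinal, table)
        for ordinal, peptide in enumerate(peptides)
    ]


def format_dta(spectrum: Spectrum) -> str:
    """Render a spectrum as DTA text (M+H and charge, then peak lines)."""
    lines = [f"{spectrum.precursor_mh:.5f} {spectrum.parent_charge}"]
    order = np.argsort(spectrum.mz, kind="stable")
    for mz, inten in zip(spectrum.mz[order], spectrum.intensity[order]):
        lines.append(f"{mz:.5f} {inten:.4f}")
    return "\n".join(lines) + "\n"


def write_spectra(simulated: Sequence[SimulatedSpectrum], directory: str | Path) -> None:
    """Write DTA files plus a tab-separated truth manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.tsv", "w") as manifest:
        manifest.write("file\tpeptide\tprotein\tcharge\tion\texpected_mz\tincluded\n")
        for sim in simulated:
            (directory / sim.spectrum.source_file).write_text(format_dta(sim.spectrum))
            for label, mz, included in sim.ion_truth:
                manifest.write(
                    f"{sim.spectrum.source_file}\t{sim.peptide.sequence}\t"
                    f"{sim.peptide.protein_id}\t{sim.parent_charge}\t"
                    f"{label}\t{mz:.5f}\t{int(included)}\n"
                )
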