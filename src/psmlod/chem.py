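"""Amino-acid mass bookkeeping and theoretical fragment-ion generation.

Monoisotopic masses are used throughout.  The ion series supported are
y, b, a (= b - CO), singly charged by default, with y2+ generated when the
parent charge is 2 or higher, plus immonium (iminium) ions and neutral-loss
variants (up to two waters and two ammonias per fragment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON",
    "WATER",
    "AMMONIA",
    "CO",
    "MONOISOTOPIC_RESIDUE_MASS",
    "AminoAcidTable",
    "ModificationSpec",
    "TheoreticalIon",
    "IonConfig",
    "peptide_mass",
    "iminium_mz",
    "generate_ion_series",
]

PROTON = 1.007276
WATER = 18.010565
AMMONIA = 17.026549
CO = 27.994915

#: Monoisotopic residue (not free amino acid) masses in Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Kyte-Doolittle hydropathy values, used only to ORDER residues; the codes
#: fed to the intensity model are evenly spaced ranks on [0, 1].
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: pKa values for ionizable groups (EMBOSS-style defaults).
DEFAULT_PKA: dict[str, float] = {
    "n_term": 8.6,
    "c_term": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}


def _hydrophobicity_ranks() -> dict[str, float]:
    # 20 distinct codes, evenly spaced on [0, 1], increasing hydrophobicity.
    # Ties in the hydropathy scale are broken alphabetically for determinism.
    order = sorted(MONOISOTOPIC_RESIDUE_MASS, key=lambda r: (KYTE_DOOLITTLE[r], r))
    return {res: i / (len(order) - 1) for i, res in enumerate(order)}


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue masses plus the auxiliary per-residue scales.

    ``hydrophobicity_rank`` maps each residue to one of 20 evenly spaced
    codes on [0, 1] in order of increasing hydrophobicity; ``pka`` holds
    pKa values for the ionizable groups used in isoelectric-point
    calculations.
    """

    residue_mass: Mapping[str, float]
    hydrophobicity_rank: Mapping[str, float]
    pka: Mapping[str, float]

    @classmethod
    def default(cls) -> "AminoAcidTable":
        return cls(
            residue_mass=dict(MONOISOTOPIC_RESIDUE_MASS),
            hydrophobicity_rank=_hydrophobicity_ranks(),
            pka=dict(DEFAULT_PKA),
        )


DEFAULT_TABLE = AminoAcidTable.default()


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable residue modification.

    ``targets`` is the set of residue codes the modification may land on;
    ``max_per_peptide`` bounds how many variable occurrences are enumerated
    per peptide.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    kind: str  # "fixed" | "variable"
    max_per_peptide: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"modification kind must be fixed|variable, got {self.kind!r}")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError("delta_mass must be finite")
        if self.kind == "variable" and self.max_per_peptide < 1:
            raise ValueError("variable modifications need max_per_peptide >= 1")
        if self.max_per_peptide < 0:
            raise ValueError("max_per_peptide must be >= 0")
        object.__setattr__(self, "targets", frozenset(self.targets))


#: Default modifications: oxidation (M) and methylation (K/R), both variable.
DEFAULT_MODIFICATIONS: tuple[ModificationSpec, ...] = (
    ModificationSpec("oxidation", 15.994915, frozenset("M"), "variable", 2),
    ModificationSpec("methylation", 14.015650, frozenset("KR"), "variable", 2),
)


@dataclass(frozen=True)
class TheoreticalIon:
    """One theoretical fragment ion.

    ``index`` is the 1-based series index (``None`` for immonium ions),
    ``n_water_loss``/``n_ammonia_loss`` count neutral losses relative to
    the base ion.
    """

    ion_type: str  # "precursor" | "iminium" | "y" | "a" | "b"
    index: int | None
    charge: int
    n_water_loss: int
    n_ammonia_loss: int
    mz: float
    fragment_sequence: str

    @property
    def label(self) -> str:
        if self.ion_type == "iminium":
            base = f"imm({self.fragment_sequence})"
        else:
            base = f"{self.ion_type}{self.index}"
        if self.charge == 2:
            base += "(2+)"
        base += "-H2O" * self.n_water_loss
        base += "-NH3" * self.n_ammonia_loss
        return base


@dataclass(frozen=True)
class IonConfig:
    """Which ion series to generate and with which loss limits."""

    ion_types: tuple[str, ...] = ("y", "b", "a")
    include_iminium: bool = False
    include_y2: bool = True  # only takes effect when parent charge >= 2
    max_water_loss: int = 0
    max_ammonia_loss: int = 0

    @classmethod
    def preliminary(cls) -> "IonConfig":
        """Ion set for preliminary scoring: y1+, b1+, iminium, conditional y2+."""
        return cls(ion_types=("y", "b"), include_iminium=True, include_y2=True)

    @classmethod
    def probability(cls, include_iminium: bool = False) -> "IonConfig":
        """Full ion set for probability scoring: y/b/a with up to two water
        and two ammonia losses, plus y2+ for multiply charged parents."""
        return cls(
            ion_types=("y", "b", "a"),
            include_iminium=include_iminium,
            include_y2=True,
            max_water_loss=2,
            max_ammonia_loss=2,
        )


def _residue_masses(
    sequence: str,
    mods: Sequence[tuple[ModificationSpec, int]] = (),
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[float]:
    masses = []
    for ch in sequence:
        try:
            masses.append(table.residue_mass[ch])
        except KeyError:
            raise ValueError(f"unknown residue code {ch!r} in sequence {sequence!r}") from None
    for spec, pos in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside sequence of length {len(sequence)}")
        masses[pos - 1] += spec.delta_mass
    return masses


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[ModificationSpec, int]] = (),
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    mass = sum(residue masses) + water + sum(modification deltas).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    return sum(_residue_masses(sequence, mods, table)) + WATER


def iminium_mz(residue: str, table: AminoAcidTable = DEFAULT_TABLE) -> float:
    """m/z of the immonium ion of a single residue (residue - CO + proton)."""
    return table.residue_mass[residue] - CO + PROTON


def _loss_variants(max_water: int, max_ammonia: int) -> Iterable[tuple[int, int]]:
    for k, j in itertools.product(range(max_water + 1), range(max_ammonia + 1)):
        yield k, j


def generate_ion_series(
    sequence: str,
    mods: Sequence[tuple[ModificationSpec, int]] = (),
    config: IonConfig = IonConfig(),
    parent_charge: int = 1,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[TheoreticalIon]:
    """Generate the theoretical ion list for a peptide.

    For a peptide of length n, y_i and b_i are produced for i = 1..n-1
    (a_i = b_i - CO).  y2+ ions are emitted only when ``parent_charge >= 2``
    and the config allows them.  Neutral-loss variants subtract
    k*water + j*ammonia from the fragment neutral mass.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    masses = _residue_masses(sequence, mods, table)
    n = len(sequence)
    ions: list[TheoreticalIon] = []

    want_y = "y" in config.ion_types
    want_b = "b" in config.ion_types
    want_a = "a" in config.ion_types
    want_y2 = config.include_y2 and parent_charge >= 2

    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    def emit(ion_type: str, index: int, charge: int, neutral: float, frag: str) -> None:
        for k, j in _loss_variants(config.max_water_loss, config.max_ammonia_loss):
            reduced = neutral - k * WATER - j * AMMONIA
            if reduced <= 0:
                continue
            mz = (reduced + charge * PROTON) / charge
            ions.append(TheoreticalIon(ion_type, index, charge, k, j, mz, frag))

    for i in range(1, n):
        b_neutral = prefix[i]  # first i residues
        y_neutral = total - prefix[n - i] + WATER  # last i residues
        if want_b:
            emit("b", i, 1, b_neutral, sequence[:i])
        if want_a:
            emit("a", i, 1, b_neutral - CO, sequence[:i])
        if want_y:
            emit("y", i, 1, y_neutral, sequence[n - i:])
            if want_y2:
                emit("y", i, 2, y_neutral, sequence[n - i:])

    if config.include_iminium:
        for res in sorted(set(sequence)):
            ions.append(
                TheoreticalIon("iminium", None, 1, 0, 0, iminium_mz(res, table), res)
            )
    return ions
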