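"""Proteome digestion, modified-peptide enumeration, and the mass-ordered index.

The index answers precursor-mass window queries by binary search and is
serialized as a versioned JSON-lines text file so that a round trip is
bitwise exact.  Decoy databases are built by reversing each protein
sequence before digestion.
"""

from __future__ import annotations

import hashlib
import io
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .chem import (
    DEFAULT_MODIFICATIONS,
    DEFAULT_TABLE,
    AminoAcidTable,
    IonConfig,
    ModificationSpec,
    generate_ion_series,
    peptide_mass,
)

__all__ = [
    "Peptide",
    "PeptideIndex",
    "digest",
    "enumerate_modified_forms",
    "build_index",
    "make_decoy_database",
    "query_by_mass",
    "save_index",
    "load_index",
]

log = logging.getLogger(__name__)

INDEX_FORMAT = "psmlod-index"
INDEX_VERSION = 1

#: Enumeration cap for variable-modification forms per base peptide.
MAX_FORMS_PER_PEPTIDE = 64

DEFAULT_MIN_LENGTH = 5
DEFAULT_MAX_LENGTH = 60


@dataclass(frozen=True)
class Peptide:
    """A digested, possibly modified peptide with pre-computed attributes."""

    sequence: str
    applied_mods: tuple[tuple[ModificationSpec, int], ...]
    neutral_mass: float
    protein_id: str
    flank_n: str
    flank_c: str
    y_series: tuple[float, ...]
    missed_cleavages: int
    is_decoy: bool = False

    @property
    def mod_deltas(self) -> tuple[tuple[ModificationSpec, int], ...]:
        return self.applied_mods


def _cleavage_segments(sequence: str) -> list[tuple[int, int]]:
    """Half-open (start, end) coordinates of tryptic segments.

    Trypsin rule: cleave after K or R unless the next residue is P.
    """
    sites = [
        i + 1
        for i, ch in enumerate(sequence)
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")
    ]
    bounds = [0] + sites
    if not sites or sites[-1] != len(sequence):
        bounds.append(len(sequence))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def digest_with_coords(sequence: str, max_missed: int = 2) -> list[tuple[int, int, int]]:
    """Tryptic digest returning (start, end, missed_cleavages) coordinate runs."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        return []
    segments = _cleavage_segments(sequence)
    out = []
    for i in range(len(segments)):
        for run in range(1, max_missed + 2):
            if i + run > len(segments):
                break
            out.append((segments[i][0], segments[i + run - 1][1], run - 1))
    return out


def digest(sequence: str, max_missed: int = 2) -> list[str]:
    """Peptide sequences from a tryptic digest with up to ``max_missed``
    missed cleavages."""
    return [sequence[s:e] for s, e, _ in digest_with_coords(sequence, max_missed)]


def enumerate_modified_forms(
    sequence: str,
    mod_specs: Sequence[ModificationSpec],
    protein_id: str = "",
    flank_n: str = "",
    flank_c: str = "",
    missed_cleavages: int = 0,
    is_decoy: bool = False,
    table: AminoAcidTable = DEFAULT_TABLE,
    cap: int = MAX_FORMS_PER_PEPTIDE,
) -> list[Peptide]:
    """All modified forms of a base peptide.

    Fixed mods are applied to every target residue.  Variable mods are
    enumerated over position subsets up to each spec's ``max_per_peptide``;
    a position carries at most one modification.  Enumeration is truncated
    (with a log warning) at ``cap`` forms.
    """
    fixed: list[tuple[ModificationSpec, int]] = []
    variable_choices: list[list[tuple[tuple[ModificationSpec, int], ...]]] = []
    for spec in mod_specs:
        positions = [i + 1 for i, ch in enumerate(sequence) if ch in spec.targets]
        if spec.kind == "fixed":
            fixed.extend((spec, p) for p in positions)
        else:
            combos: list[tuple[tuple[ModificationSpec, int], ...]] = []
            for k in range(0, min(spec.max_per_peptide, len(positions)) + 1):
                combos.extend(
                    tuple((spec, p) for p in chosen)
                    for chosen in itertools.combinations(positions, k)
                )
            variable_choices.append(combos)

    fixed_positions = {p for _, p in fixed}
    forms: list[Peptide] = []
    truncated = False
    for combo in itertools.product(*variable_choices):
        mods = list(fixed)
        positions = set(fixed_positions)
        ok = True
        for group in combo:
            for spec, p in group:
                if p in positions:
                    ok = False
                    break
                positions.add(p)
                mods.append((spec, p))
            if not ok:
                break
        if not ok:
            continue
        if len(forms) >= cap:
            truncated = True
            break
        mods.sort(key=lambda sp: (sp[1], sp[0].name))
        forms.append(
            _make_peptide(
                sequence, tuple(mods), protein_id, flank_n, flank_c,
                missed_cleavages, is_decoy, table,
            )
        )
    if truncated:
        log.warning(
            "modification enumeration for %s truncated at %d forms", sequence, cap
        )
    return forms


def _make_peptide(
    sequence: str,
    mods: tuple[tuple[ModificationSpec, int], ...],
    protein_id: str,
    flank_n: str,
    flank_c: str,
    missed_cleavages: int,
    is_decoy: bool,
    table: AminoAcidTable,
) -> Peptide:
    mass = peptide_mass(sequence, mods, table)
    y_only = IonConfig(ion_types=("y",), include_y2=False)
    ions = generate_ion_series(sequence, mods, y_only, parent_charge=1, table=table)
    y_series = tuple(ion.mz for ion in sorted(ions, key=lambda i: i.index))
    return Peptide(
        sequence=sequence,
        applied_mods=mods,
        neutral_mass=mass,
        protein_id=protein_id,
        flank_n=flank_n,
        flank_c=flank_c,
        y_series=y_series,
        missed_cleavages=missed_cleavages,
        is_decoy=is_decoy,
    )


@dataclass
class PeptideIndex:
    """Mass-ordered peptide records with window-query support."""

    records: list[Peptide]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda p: (p.neutral_mass, p.sequence, p.protein_id)
        )
        self._masses = np.array([p.neutral_mass for p in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def masses(self) -> np.ndarray:
        return self._masses


def query_by_mass(index: PeptideIndex, neutral_mass: float, tolerance: float) -> list[Peptide]:
    """Records with |mass - neutral_mass| <= tolerance, via binary search."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    lo = int(np.searchsorted(index.masses, neutral_mass - tolerance, side="left"))
    hi = int(np.searchsorted(index.masses, neutral_mass + tolerance, side="right"))
    return index.records[lo:hi]


def _iter_fasta(fasta: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (protein_id, sequence) from FASTA text or a file path."""
    if isinstance(fasta, Path) or (isinstance(fasta, str) and not fasta.lstrip().startswith(">")):
        handle: io.TextIOBase = open(fasta)
    else:
        handle = io.StringIO(fasta)
    with handle:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq).upper()


def _fasta_text(fasta: str | Path) -> str:
    if isinstance(fasta, Path) or (isinstance(fasta, str) and not fasta.lstrip().startswith(">")):
        return Path(fasta).read_text()
    return fasta


def build_index(
    fasta: str | Path,
    mod_specs: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    max_missed: int = 2,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    decoy: bool = False,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> PeptideIndex:
    """Digest a FASTA proteome into a mass-ordered modified-peptide index.

    With ``decoy=True`` every protein sequence is reversed before digestion
    and the records are flagged.  Two residues of flanking context are kept
    on each side for report rendering.
    """
    records: list[Peptide] = []
    skipped = 0
    for protein_id, seq in _iter_fasta(fasta):
        if decoy:
            seq = seq[::-1]
            protein_id = f"rev_{protein_id}"
        if any(ch not in table.residue_mass for ch in seq):
            skipped += 1
            continue
        for start, end, missed in digest_with_coords(seq, max_missed):
            pep_seq = seq[start:end]
            if not (min_length <= len(pep_seq) <= max_length):
                continue
            records.extend(
                enumerate_modified_forms(
                    pep_seq,
                    mod_specs,
                    protein_id=protein_id,
                    flank_n=seq[max(0, start - 2):start],
                    flank_c=seq[end:end + 2],
                    missed_cleavages=missed,
                    is_decoy=decoy,
                    table=table,
                )
            )
    if skipped:
        log.warning("skipped %d proteins containing non-standard residues", skipped)
    metadata = {
        "enzyme": "trypsin (cleave after K/R, not before P)",
        "max_missed": max_missed,
        "min_length": min_length,
        "max_length": max_length,
        "decoy": decoy,
        "modifications": [_mod_to_json(m) for m in mod_specs],
        "fasta_sha1": hashlib.sha1(_fasta_text(fasta).encode()).hexdigest(),
    }
    return PeptideIndex(records, metadata)


def make_decoy_database(
    fasta: str | Path,
    mod_specs: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    **kwargs,
) -> PeptideIndex:
    """Reversed-protein decoy index built with the same digestion settings."""
    return build_index(fasta, mod_specs, decoy=True, **kwargs)


# ---------------------------------------------------------------------------
# serialization (JSON lines: header record then one record per peptide)

def _mod_to_json(spec: ModificationSpec) -> dict:
    return {
        "name": spec.name,
        "delta_mass": spec.delta_mass,
        "targets": "".join(sorted(spec.targets)),
        "kind": spec.kind,
        "max_per_peptide": spec.max_per_peptide,
    }


def _mod_from_json(obj: dict) -> ModificationSpec:
    return ModificationSpec(
        obj["name"], obj["delta_mass"], frozenset(obj["targets"]),
        obj["kind"], obj["max_per_peptide"],
    )


def _peptide_to_json(p: Peptide) -> dict:
    return {
        "sequence": p.sequence,
        "mods": [[_mod_to_json(spec), pos] for spec, pos in p.applied_mods],
        "neutral_mass": p.neutral_mass,
        "protein_id": p.protein_id,
        "flank_n": p.flank_n,
        "flank_c": p.flank_c,
        "y_series": list(p.y_series),
        "missed_cleavages": p.missed_cleavages,
        "is_decoy": p.is_decoy,
    }


def _peptide_from_json(obj: dict) -> Peptide:
    return Peptide(
        sequence=obj["sequence"],
        applied_mods=tuple((_mod_from_json(m), pos) for m, pos in obj["mods"]),
        neutral_mass=obj["neutral_mass"],
        protein_id=obj["protein_id"],
        flank_n=obj["flank_n"],
        flank_c=obj["flank_c"],
        y_series=tuple(obj["y_series"]),
        missed_cleavages=obj["missed_cleavages"],
        is_decoy=obj["is_decoy"],
    )


def save_index(index: PeptideIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = {"format": INDEX_FORMAT, "version": INDEX_VERSION,
                  "n_records": len(index), "metadata": index.metadata}
        fh.write(json.dumps(header) + "\n")
        for record in index.records:
            fh.write(json.dumps(_peptide_to_json(record)) + "\n")


def load_index(path: str | Path) -> PeptideIndex:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != INDEX_FORMAT:
            raise ValueError(f"{path}: not a peptide index file")
        if header.get("version") != INDEX_VERSION:
            raise ValueError(f"{path}: unsupported index version {header.get('version')}")
        records = [_peptide_from_json(json.loads(line)) for line in fh if line.strip()]
    return PeptideIndex(records, header.get("metadata", {}))
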