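"""Fragmentation-property exploration: isoelectric points of complementary
y/b fragments at sites where only one of the pair was detected."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chem import DEFAULT_TABLE, AminoAcidTable
from .tables import Assignment

__all__ = [
    "ComplementaryPairRecord",
    "net_charge",
    "isoelectric_point",
    "complementary_pair_table",
    "write_pair_table",
]

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class ComplementaryPairRecord:
    """One fragmentation site where exactly one of the y/b pair was seen."""

    spectrum_id: str
    parent_length: int
    site_fraction: float  # b-fragment length / parent length, in (0, 1)
    pi_y: float
    pi_b: float
    relative_pi: float  # pi_y / pi_b
    delta_pi: float  # pi_y - pi_b
    observed_ion: str  # "y-only" | "b-only"


def net_charge(sequence: str, pH: float, table: AminoAcidTable = DEFAULT_TABLE) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Terms: free N-terminus, free C-terminus, and the ionizable side chains
    K/R/H (positive) and D/E/C/Y (negative).
    """
    pka = table.pka
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - pH))
    for res in sequence:
        if res in _POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka[res]))
        elif res in _NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (pka[res] - pH))
    return charge


def isoelectric_point(
    sequence: str,
    table: AminoAcidTable = DEFAULT_TABLE,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique; the
    iteration stops when |net charge| < ``tolerance``.
    """
    if not sequence:
        raise ValueError("empty fragment sequence")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, table)
        if abs(q) < tolerance:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def complementary_pair_table(
    assignments: Sequence[Assignment],
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[ComplementaryPairRecord]:
    """One record per fragmentation site where exactly one of the
    complementary ions {y_(n-i), b_i} was matched.

    Any matched variant (charge state or neutral loss) of the ion counts
    as detected.  Fragment termini are treated as standard amino/carboxy
    groups for the pI calculation.
    """
    records: list[ComplementaryPairRecord] = []
    for assignment in assignments:
        seq = assignment.peptide.sequence
        n = len(seq)
        detected: set[tuple[str, int]] = {
            (m.ion.ion_type, m.ion.index)
            for m in assignment.matches
            if m.ion.ion_type in ("y", "b") and m.ion.index is not None
        }
        for i in range(1, n):
            has_b = ("b", i) in detected
            has_y = ("y", n - i) in detected
            if has_b == has_y:
                continue
            pi_b = isoelectric_point(seq[:i], table)
            pi_y = isoelectric_point(seq[i:], table)
            records.append(
                ComplementaryPairRecord(
                    spectrum_id=assignment.spectrum_id,
                    parent_length=n,
                    site_fraction=i / n,
                    pi_y=pi_y,
                    pi_b=pi_b,
                    relative_pi=pi_y / pi_b,
                    delta_pi=pi_y - pi_b,
                    observed_ion="y-only" if has_y else "b-only",
                )
            )
    return records


def write_pair_table(records: Sequence[ComplementaryPairRecord], stream) -> None:
    """Tab-separated output of the complementary-pair table."""
    stream.write(
        "spectrum\tparent_length\tsite_fraction\tpi_y\tpi_b\t"
        "relative_pi\tdelta_pi\tobserved_ion\n"
    )
    for r in records:
        stream.write(
            f"{r.spectrum_id}\t{r.parent_length}\t{r.site_fraction:.4f}\t"
            f"{r.pi_y:.4f}\t{r.pi_b:.4f}\t{r.relative_pi:.4f}\t"
            f"{r.delta_pi:.4f}\t{r.observed_ion}\n"
        )
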