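"""Human-readable per-identification reports and the machine summary table.

The report is a fixed-format text block per identification: fragments are
ranked by observed intensity with observed (obsMZ) and expected (expMZ)
m/z values, the peptide LOD is rendered as the sum of the rendered
fragment LODs, and flanking-context dots mark residues not present in the
peptide itself.  m/z values use 4 decimals, LOD and Z values use 2, so
identical runs produce byte-identical output.
"""

from __future__ import annotations

import re
from typing import Sequence, TextIO

from .candidates import Candidate

__all__ = ["write_match_report", "parse_match_reports", "write_summary"]

_BLOCK_SEP = "-" * 60


def _render_seq(candidate: Candidate) -> str:
    p = candidate.peptide
    return f"{p.flank_n}.{p.sequence}.{p.flank_c}"


def _render_mods(candidate: Candidate) -> str:
    mods = candidate.peptide.applied_mods
    if not mods:
        return "none"
    return ",".join(f"{spec.name}@{pos}({spec.delta_mass:+.4f})" for spec, pos in mods)


def write_match_report(candidate: Candidate, stream: TextIO, metric: str = "1") -> None:
    """Write one identification block.

    The rendered peptide LOD is the sum of the 2-decimal rendered fragment
    LODs so the printed total always equals the printed parts.
    """
    p = candidate.peptide
    stream.write(f"{_BLOCK_SEP}\n")
    stream.write(f"file: {candidate.spectrum_ref}\n")
    stream.write(f"seq: {_render_seq(candidate)}\n")
    stream.write(f"mods: {_render_mods(candidate)}\n")
    stream.write(f"pmass: {p.neutral_mass:.4f}\n")
    stream.write(f"protein: {p.protein_id}\n")
    stream.write(f"metric: {metric}\n")
    stream.write(f"yhits: {candidate.y_hits}\n")
    stream.write(f"prelim: {candidate.preliminary_score:.4f}\n")
    stream.write("ion\tobsMZ\texpMZ\tintensity\tLOD\n")
    total = 0.0
    for m in sorted(candidate.matches, key=lambda m: (-m.observed_intensity, m.ion.mz)):
        rendered = round(m.fragment_lod, 2)
        total += rendered
        stream.write(
            f"{m.ion.label}\t{m.observed_mz:.4f}\t{m.ion.mz:.4f}\t"
            f"{m.observed_intensity:.2f}\t{rendered:.2f}\n"
        )
    stream.write(f"peptideLOD: {round(total, 2):.2f}\n")
    if candidate.z_score is None:
        stream.write("Z: NA\n")
    else:
        stream.write(f"Z: {candidate.z_score:.2f}\n")
    if candidate.intensity_z is not None:
        stream.write(f"intensityZ: {candidate.intensity_z:.2f}\n")
        stream.write(f"combinedZ: {candidate.combined_z:.2f}\n")


_FIELD_RE = re.compile(r"^(\w+): (.*)$")


def parse_match_reports(text: str) -> list[dict]:
    """Parse report text back into dicts (round-trip of the rendered fields).

    Each dict holds the header fields plus ``fragments`` as a list of
    (ion label, obsMZ, expMZ, intensity, LOD) tuples.
    """
    blocks = [b for b in text.split(_BLOCK_SEP) if b.strip()]
    out = []
    for block in blocks:
        record: dict = {"fragments": []}
        in_table = False
        for line in block.strip().splitlines():
            if line.startswith("ion\t"):
                in_table = True
                continue
            m = _FIELD_RE.match(line)
            if m:
                in_table = False
                key, value = m.groups()
                if key in ("pmass", "prelim", "peptideLOD", "intensityZ", "combinedZ"):
                    record[key] = float(value)
                elif key == "Z":
                    record[key] = None if value == "NA" else float(value)
                elif key == "yhits":
                    record[key] = int(value)
                elif key == "seq":
                    record[key] = value
                    record["sequence"] = value.split(".")[1]
                else:
                    record[key] = value
            elif in_table and line.strip():
                label, obs, exp, inten, lod = line.split("\t")
                record["fragments"].append(
                    (label, float(obs), float(exp), float(inten), float(lod))
                )
        out.append(record)
    return out


def write_summary(results: dict[str, Sequence[Candidate]], stream: TextIO) -> None:
    """One tab-separated row per spectrum: its best candidate and scores."""
    stream.write("spectrum\tpeptide\tprotein\tlod\tz\tintensity_z\tprelim\ty_hits\tn_matches\n")
    for spectrum_id in sorted(results):
        candidates = results[spectrum_id]
        if not candidates:
            stream.write(f"{spectrum_id}\t-\t-\tNA\tNA\tNA\tNA\tNA\t0\n")
            continue
        best = candidates[0]
        z = "NA" if best.z_score is None else f"{best.z_score:.4f}"
        iz = "NA" if best.intensity_z is None else f"{best.intensity_z:.4f}"
        stream.write(
            f"{spectrum_id}\t{best.peptide.sequence}\t{best.peptide.protein_id}\t"
            f"{best.peptide_lod:.4f}\t{z}\t{iz}\t{best.preliminary_score:.4f}\t"
            f"{best.y_hits}\t{len(best.matches)}\n"
        )
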