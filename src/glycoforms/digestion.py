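"""In-silico tryptic digestion and N-glycosylation sequon detection.

Trypsin cleaves after Lys and Arg; the default here is the plain rule with
no proline suppression, matching common search-engine settings (a
``suppress_proline`` flag restores the classical KP/RP exception). Sequons
are N-X-S/T with X != P; a sequon truncated by the peptide boundary is not
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "PeptideCandidate",
    "tryptic_digest",
    "find_sequons",
    "digest_fasta",
    "candidates_to_tsv",
]


@dataclass(frozen=True)
class PeptideCandidate:
    """A tryptic peptide with its parent coordinates (0-based, half-open)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    sequon_positions: tuple[int, ...] = ()
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.missed_cleavages < 0:
            raise ValueError("missed cleavage count must be non-negative")
        for i in self.sequon_positions:
            if self.sequence[i] != "N":
                raise ValueError(f"sequon position {i} is not N in {self.sequence!r}")


def _cleavage_sites(protein: str, suppress_proline: bool) -> list[int]:
    """Positions after which trypsin cuts (cut between i and i+1)."""
    sites = []
    for i, ch in enumerate(protein[:-1]):
        if ch in "KR":
            if suppress_proline and protein[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def tryptic_digest(
    protein: str,
    max_missed: int = 2,
    suppress_proline: bool = False,
    protein_id: str = "",
) -> list[PeptideCandidate]:
    """All tryptic peptides of ``protein`` with 0..max_missed missed cleavages.

    Peptides are bounded by cleavage sites (after K/R) or the termini; the
    output is duplicate-free per (start, end) and sorted by coordinates.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bounds = [0] + _cleavage_sites(protein, suppress_proline) + [len(protein)]
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            start, end = bounds[a], bounds[b]
            seq = protein[start:end]
            out.append(
                PeptideCandidate(
                    sequence=seq,
                    start=start,
                    end=end,
                    missed_cleavages=b - a - 1,
                    sequon_positions=_scan_sequons(seq),
                    protein_id=protein_id,
                )
            )
    return out


def _scan_sequons(seq: str) -> tuple[int, ...]:
    return tuple(
        i
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    )


def find_sequons(peptide: PeptideCandidate | str) -> tuple[int, ...]:
    """Peptide-local indices of N in N-X-S/T (X != P) sequons."""
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    return _scan_sequons(seq)


def digest_fasta(
    path: str | Path,
    max_missed: int = 2,
    suppress_proline: bool = False,
) -> list[PeptideCandidate]:
    """Digest every record of a (multi-)FASTA file.

    Identifiers are preserved verbatim (full header up to the first space).
    """
    from pyteomics import fasta

    out: list[PeptideCandidate] = []
    with fasta.read(str(path)) as reader:
        for header, seq in reader:
            protein_id = header.split()[0]
            out.extend(
                tryptic_digest(
                    seq.upper(), max_missed, suppress_proline, protein_id=protein_id
                )
            )
    return out


def candidates_to_tsv(candidates: Iterable[PeptideCandidate], out: TextIO) -> None:
    """Write candidates as TSV: protein_id, sequence, start, end, missed, sequons."""
    out.write("protein_id\tsequence\tstart\tend\tmissed\tsequons\n")
    for c in candidates:
        sequons = ",".join(map(str, c.sequon_positions))
        out.write(
            f"{c.protein_id}\t{c.sequence}\t{c.start}\t{c.end}\t{c.missed_cleavages}\t{sequons}\n"
        )
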