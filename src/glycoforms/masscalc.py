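"""Monoisotopic mass arithmetic for glycopeptides and their diagnostic ions.

All masses are monoisotopic daltons. The instrument context is a
high-resolution Orbitrap workflow, where identification and verification are
done with ppm-level tolerances; average masses are deliberately not
supported. The built-in residue and monosaccharide tables can be overridden
from a YAML/JSON mapping for non-standard chemistries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "PROTON",
    "WATER",
    "ResidueMassTable",
    "MonosaccharideMassTable",
    "ModificationSet",
    "peptide_mass",
    "glycan_mass",
    "precursor_mz",
    "diagnostic_ion_mz",
    "ppm_match",
    "DIAGNOSTIC_ION_KINDS",
]

#: Mass of a proton (charge carrier), Da.
PROTON = 1.007276466

#: Mass of water (peptide condensation terminus), Da.
WATER = 18.010565

# Monoisotopic residue masses, Da (standard 20 amino acids).
# Table version 1: CODATA-consistent elemental masses.
_AA_MONO = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# Monosaccharide residue masses, Da (glycosidic, i.e. anhydro).
_SUGAR_MONO = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "Neu5Ac": 291.095417,
    "Neu5Gc": 307.090331,
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Amino-acid residue masses plus the water and proton constants."""

    amino_acid_masses: Mapping[str, float] = field(default_factory=lambda: dict(_AA_MONO))
    water: float = WATER
    proton: float = PROTON

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.amino_acid_masses.values()):
            raise ValueError("residue masses must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueMassTable":
        data = _load_mapping(path)
        return cls(
            amino_acid_masses=dict(data.get("amino_acid_masses", _AA_MONO)),
            water=float(data.get("water", WATER)),
            proton=float(data.get("proton", PROTON)),
        )


@dataclass(frozen=True)
class MonosaccharideMassTable:
    """Monosaccharide (anhydro) residue masses."""

    masses: Mapping[str, float] = field(default_factory=lambda: dict(_SUGAR_MONO))

    def __getitem__(self, key: str) -> float:
        return self.masses[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "MonosaccharideMassTable":
        data = _load_mapping(path)
        merged = dict(_SUGAR_MONO)
        merged.update({k: float(v) for k, v in data.get("masses", data).items()})
        return cls(masses=merged)


def _load_mapping(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ModificationSet:
    """Fixed and variable peptide modifications.

    ``fixed``: list of ``(residue, delta_da)`` applied to every occurrence.
    ``variable``: list of ``(residue, delta_da, max_occurrences)``; variable
    mods shift candidate masses but are not applied by :func:`peptide_mass`,
    which returns the unmodified-variable (fixed-only) mass.
    """

    fixed: tuple[tuple[str, float], ...] = ()
    variable: tuple[tuple[str, float, int], ...] = ()

    @classmethod
    def default(cls) -> "ModificationSet":
        """Methylthio-Cys fixed; Met oxidation variable, at most once."""
        return cls(
            fixed=(("C", 45.987721),),
            variable=(("M", 15.994915, 1),),
        )


_DEFAULT_RESIDUES = ResidueMassTable()
_DEFAULT_SUGARS = MonosaccharideMassTable()


def peptide_mass(
    sequence: str,
    mods: ModificationSet | None = None,
    table: ResidueMassTable = _DEFAULT_RESIDUES,
) -> float:
    """Neutral monoisotopic mass of a peptide with fixed modifications applied.

    Parameters
    ----------
    sequence : residue string (single-letter codes).
    mods : fixed/variable modification set; only fixed deltas are added here.
    table : residue mass table; defaults to the built-in version-1 table.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = table.water
    aa = table.amino_acid_masses
    for ch in sequence:
        try:
            mass += aa[ch]
        except KeyError:
            raise ValueError(f"unknown residue letter {ch!r} in {sequence!r}") from None
    if mods is not None:
        for residue, delta in mods.fixed:
            mass += delta * sequence.count(residue)
    return mass


def glycan_mass(comp, table: MonosaccharideMassTable = _DEFAULT_SUGARS) -> float:
    """Neutral residue-mass sum of a glycan composition.

    ``comp`` is anything exposing ``hexnac, hex, fuc, neu5ac, neu5gc`` counts
    (a :class:`glycoforms.glycospace.GlycanComposition` or a mapping).
    """
    counts = _as_counts(comp)
    if any(c < 0 for c in counts.values()):
        raise ValueError(f"negative monosaccharide count in {counts}")
    return (
        counts["hexnac"] * table["HexNAc"]
        + counts["hex"] * table["Hex"]
        + counts["fuc"] * table["Fuc"]
        + counts["neu5ac"] * table["Neu5Ac"]
        + counts["neu5gc"] * table["Neu5Gc"]
    )


def _as_counts(comp) -> dict[str, int]:
    if isinstance(comp, Mapping):
        base = {"hexnac": 0, "hex": 0, "fuc": 0, "neu5ac": 0, "neu5gc": 0}
        unknown = set(comp) - set(base)
        if unknown:
            raise ValueError(f"unknown monosaccharide keys {sorted(unknown)}")
        base.update(comp)
        return base
    return {
        "hexnac": comp.hexnac,
        "hex": comp.hex,
        "fuc": comp.fuc,
        "neu5ac": comp.neu5ac,
        "neu5gc": comp.neu5gc,
    }


def precursor_mz(peptide_mass_da: float, glycan_mass_da: float, charge: int) -> float:
    """m/z of the protonated glycopeptide precursor at the given charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_mass_da + glycan_mass_da + charge * PROTON) / charge


#: Diagnostic fragment ions used for glycopeptide verification, all singly
#: protonated. ``Y1``/``Y1_fuc`` need the peptide mass; the rest are fixed
#: oxonium / oxonium-like masses.
DIAGNOSTIC_ION_KINDS = (
    "Y1",
    "Y1_fuc",
    "antenna_fuc",
    "neu5ac_oxonium",
    "neu5ac_oxonium_minus_water",
    "neu5gc_oxonium",
    "neu5gc_oxonium_minus_water",
)


def diagnostic_ion_mz(
    kind: str,
    peptide_mass_da: float | None = None,
    table: MonosaccharideMassTable = _DEFAULT_SUGARS,
) -> float:
    """Singly protonated m/z of a diagnostic glycopeptide fragment ion.

    ``Y1`` is peptide + GlcNAc (HexNAc); ``Y1_fuc`` adds a core fucose.
    ``antenna_fuc`` is the HexNAc+Hex+Fuc oxonium at m/z 512.20 diagnostic of
    antenna fucosylation. The sialic oxonium ions (Neu5Ac 292.10/274.09,
    Neu5Gc 308.10/290.09) are required in pairs during verification.
    """
    if kind in ("Y1", "Y1_fuc"):
        if peptide_mass_da is None:
            raise ValueError(f"{kind} requires a peptide mass")
        mz = peptide_mass_da + table["HexNAc"] + PROTON
        if kind == "Y1_fuc":
            mz += table["Fuc"]
        return mz
    if kind == "antenna_fuc":
        return table["HexNAc"] + table["Hex"] + table["Fuc"] + PROTON
    if kind == "neu5ac_oxonium":
        return table["Neu5Ac"] + PROTON
    if kind == "neu5ac_oxonium_minus_water":
        return table["Neu5Ac"] + PROTON - WATER
    if kind == "neu5gc_oxonium":
        return table["Neu5Gc"] + PROTON
    if kind == "neu5gc_oxonium_minus_water":
        return table["Neu5Gc"] + PROTON - WATER
    raise ValueError(f"unknown diagnostic ion kind {kind!r}")


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff |observed - theoretical| is within ``tol_ppm`` of theoretical.

    The window is inclusive and symmetric in the sign of the error.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    if tol_ppm <= 0:
        raise ValueError(f"tolerance must be positive, got {tol_ppm}")
    return abs(observed - theoretical) / theoretical * 1e6 <= tol_ppm
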