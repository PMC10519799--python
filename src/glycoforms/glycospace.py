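"""Constrained N-glycan composition space and G0/G1/G2/S nomenclature.

The composition space emulated here is the biantennary complex-type space of
murine IgG-Fc glycans: a HexNAc2Hex3 core carrying two GlcNAc antennae, each
optionally extended GlcNAc -> Gal -> sialic acid, plus optional core fucose
and optional bisecting GlcNAc. Sialic acids are Neu5Gc (dominant in mouse) or
Neu5Ac, never mixed on one glycan by default. Oligomannose (Man5-Man9) and
simple hybrid structures can be enumerated behind flags but are excluded from
the G-labeling, which is defined only for complex biantennary forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GlycanComposition",
    "GlycoformLabel",
    "enumerate_biantennary",
    "enumerate_oligomannose",
    "enumerate_hybrid",
    "label_glycoform",
    "composition_from_label",
    "parse_composition",
    "format_composition",
]

# Biantennary complex core: 2 core GlcNAc + 2 antenna GlcNAc, 3 core mannoses.
_CORE_HEXNAC = 4
_CORE_HEX = 3


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide count vector with a structural class label.

    ``hexnac`` includes the bisecting GlcNAc when ``bisecting`` is set, since
    composition-level MS cannot distinguish the isomers; the flag records the
    structural interpretation without changing the mass.
    """

    hexnac: int
    hex: int
    fuc: int = 0
    neu5ac: int = 0
    neu5gc: int = 0
    bisecting: int = 0
    glycan_class: str = "complex"

    def __post_init__(self) -> None:
        counts = (self.hexnac, self.hex, self.fuc, self.neu5ac, self.neu5gc)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in {self}")
        if self.fuc > 1:
            raise ValueError("at most one fucose is allowed")
        if self.neu5ac + self.neu5gc > 3:
            raise ValueError("at most three sialic acids are allowed")
        if self.neu5ac > 0 and self.neu5gc > 0:
            raise ValueError("Neu5Ac and Neu5Gc may not be mixed on one glycan")
        if self.bisecting not in (0, 1):
            raise ValueError("bisecting is a 0/1 flag")
        if self.glycan_class not in ("complex", "hybrid", "oligomannose"):
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")

    @property
    def sialic(self) -> int:
        return self.neu5ac + self.neu5gc

    def __str__(self) -> str:
        return format_composition(self)


@dataclass(frozen=True)
class GlycoformLabel:
    """Shorthand glycoform name on the biantennary core.

    ``galactose_state`` is G0/G1/G2 (terminal galactoses); ``sialo_state``
    counts sialic acids (S1/S2); fucosylation and bisection are carried as
    flags. Non-biantennary input is labelled ``"other"``.
    """

    galactose_state: str  # "G0" | "G1" | "G2" | "other"
    sialo_state: int = 0
    fucosylated: bool = False
    bisected: bool = False

    @property
    def name(self) -> str:
        if self.galactose_state == "other":
            return "other"
        name = self.galactose_state
        if self.sialo_state:
            name += f"S{self.sialo_state}"
        if self.fucosylated:
            name += "F"
        if self.bisected:
            name += "B"
        return name

    def __str__(self) -> str:
        return self.name


def enumerate_biantennary(
    max_sialic: int = 2,
    allow_fuc: bool = True,
    allow_bisect: bool = True,
    sialic_kind: str = "neu5gc",
) -> list[GlycanComposition]:
    """Enumerate complex biantennary compositions under the stated constraints.

    Each of the two antennae is GlcNAc, optionally galactosylated; each
    galactose optionally sialylated, so sialic <= galactose <= 2. Core fucose
    and bisecting GlcNAc are on/off. The output is duplicate-free and sorted
    canonically (lexicographic on (hexnac, hex, fuc, sialic)).
    """
    if max_sialic < 0 or max_sialic > 3:
        raise ValueError("max_sialic must be within 0..3")
    if sialic_kind not in ("neu5ac", "neu5gc"):
        raise ValueError(f"unknown sialic kind {sialic_kind!r}")
    out = set()
    for gal in range(3):  # galactoses on the two antennae
        for sia in range(min(gal, max_sialic) + 1):
            for fuc in range(2 if allow_fuc else 1):
                for bis in range(2 if allow_bisect else 1):
                    out.add(
                        GlycanComposition(
                            hexnac=_CORE_HEXNAC + bis,
                            hex=_CORE_HEX + gal,
                            fuc=fuc,
                            neu5ac=sia if sialic_kind == "neu5ac" else 0,
                            neu5gc=sia if sialic_kind == "neu5gc" else 0,
                            bisecting=bis,
                        )
                    )
    return sorted(out, key=_canonical_key)


def enumerate_oligomannose(min_man: int = 5, max_man: int = 9) -> list[GlycanComposition]:
    """Man5-Man9 series: HexNAc2 Hex(n)."""
    return [
        GlycanComposition(hexnac=2, hex=n, glycan_class="oligomannose")
        for n in range(min_man, max_man + 1)
    ]


def enumerate_hybrid(
    max_sialic: int = 1, allow_fuc: bool = True
) -> list[GlycanComposition]:
    """Simple hybrid forms: one complex antenna, 1-2 extra core mannoses."""
    out = set()
    for extra_man in (1, 2):
        for gal in range(2):
            for sia in range(min(gal, max_sialic) + 1):
                for fuc in range(2 if allow_fuc else 1):
                    out.add(
                        GlycanComposition(
                            hexnac=3,
                            hex=_CORE_HEX + extra_man + gal,
                            fuc=fuc,
                            neu5gc=sia,
                            glycan_class="hybrid",
                        )
                    )
    return sorted(out, key=_canonical_key)


def _canonical_key(c: GlycanComposition):
    return (c.hexnac, c.hex, c.fuc, c.sialic, c.glycan_class)


def label_glycoform(comp: GlycanComposition) -> GlycoformLabel:
    """Map a composition to its G0/G1/G2 (S1/S2) glycoform label.

    Galactose count is Hex beyond the three core mannoses; the sialo state is
    the total sialic-acid count. Hybrid/oligomannose input, or anything not
    explicable on the biantennary core, is labelled ``"other"`` rather than
    dropped.
    """
    if comp.glycan_class != "complex":
        return GlycoformLabel("other")
    gal = comp.hex - _CORE_HEX
    expected_hexnac = _CORE_HEXNAC + comp.bisecting
    if gal not in (0, 1, 2) or comp.hexnac != expected_hexnac or comp.sialic > gal:
        return GlycoformLabel("other")
    return GlycoformLabel(
        galactose_state=f"G{gal}",
        sialo_state=comp.sialic,
        fucosylated=comp.fuc > 0,
        bisected=comp.bisecting > 0,
    )


def composition_from_label(
    label: GlycoformLabel, sialic_kind: str = "neu5gc"
) -> GlycanComposition:
    """Inverse of :func:`label_glycoform` on the biantennary core."""
    if label.galactose_state == "other":
        raise ValueError("'other' does not correspond to a unique composition")
    gal = int(label.galactose_state[1])
    bis = 1 if label.bisected else 0
    return GlycanComposition(
        hexnac=_CORE_HEXNAC + bis,
        hex=_CORE_HEX + gal,
        fuc=1 if label.fucosylated else 0,
        neu5ac=label.sialo_state if sialic_kind == "neu5ac" else 0,
        neu5gc=label.sialo_state if sialic_kind == "neu5gc" else 0,
        bisecting=bis,
    )


# ---------------------------------------------------------------------------
# Byonic-style composition strings, e.g. "HexNAc(4)Hex(5)Fuc(1)NeuGc(2)".

_FIELD_TO_TOKEN = (
    ("hexnac", "HexNAc"),
    ("hex", "Hex"),
    ("fuc", "Fuc"),
    ("neu5ac", "NeuAc"),
    ("neu5gc", "NeuGc"),
)
_TOKEN_TO_FIELD = {
    "hexnac": "hexnac",
    "hex": "hex",
    "fuc": "fuc",
    "dhex": "fuc",
    "neuac": "neu5ac",
    "neu5ac": "neu5ac",
    "neugc": "neu5gc",
    "neu5gc": "neu5gc",
}
_TOKEN_RE = re.compile(r"([A-Za-z0-9]+?)\((\d+)\)")


def format_composition(comp: GlycanComposition) -> str:
    """Serialize as a Byonic-style string; zero counts are omitted.

    The bisecting GlcNAc is already folded into the HexNAc count, so the
    string is isomer-blind by construction.
    """
    parts = []
    for field_name, token in _FIELD_TO_TOKEN:
        n = getattr(comp, field_name)
        if n:
            parts.append(f"{token}({n})")
    return "".join(parts) or "Empty"


def parse_composition(text: str, glycan_class: str = "complex") -> GlycanComposition:
    """Parse a Byonic-style composition string. Round-trips with
    :func:`format_composition` (bisecting flag excepted: it is not encoded)."""
    counts = {"hexnac": 0, "hex": 0, "fuc": 0, "neu5ac": 0, "neu5gc": 0}
    if text.strip() in ("", "Empty"):
        return GlycanComposition(hexnac=0, hex=0, glycan_class=glycan_class)
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse composition string {text!r}")
        token = m.group(1).lower()
        if token not in _TOKEN_TO_FIELD:
            raise ValueError(f"unknown monosaccharide token {m.group(1)!r} in {text!r}")
        counts[_TOKEN_TO_FIELD[token]] += int(m.group(2))
        pos = m.end()
    if pos != len(text.strip()):
        raise ValueError(f"cannot parse composition string {text!r}")
    return GlycanComposition(glycan_class=glycan_class, **counts)
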