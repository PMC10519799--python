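"""Glycopeptide acceptance filtering and diagnostic-ion verification.

Search-engine glycopeptide hits are notoriously unreliable without fragment
level evidence. The acceptance filter used here has two stages:

1. *Score and presence*: a (sample, peptide, glycan) glycoform is retained
   only if it was identified with a score above threshold in at least
   ``min_injections`` of the sample's replicate injections. Once retained,
   all of its observations are kept for quantitation.
2. *Diagnostic ions*: every retained hit's MS2 spectrum must contain the
   peptide+GlcNAc Y1 ion; fucosylated compositions must additionally show
   the Y1+Fuc ion (core fucosylation) or the m/z 512.20 HexNAc+Hex+Fuc ion
   (antenna fucosylation); Neu5Gc compositions must show both m/z 290.09 and
   308.10, and Neu5Ac compositions both m/z 274.09 and 292.10.

What is often done by eye is implemented as a deterministic rule engine:
every verdict carries a machine-readable audit trail, so a rejected spectrum
can always be traced to the rule and ion that failed.

Scores: commercial search-engine scores (e.g. Byonic's, for which the
conventional acceptance threshold is 300) can be imported from TSV. For
spectra identified in-house, :func:`surrogate_score` provides a documented
replacement — the count of matched glycan Y-ion ladder peaks, each weighted
by -log10 of its ppm error (floored at 0.1 ppm). The two scales are not
comparable; configure ``score_min`` accordingly.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import masscalc
from .digestion import PeptideCandidate, find_sequons
from .glycospace import GlycanComposition, parse_composition

__all__ = [
    "ToleranceConfig",
    "Ms2Spectrum",
    "IdentifiedGlycopeptide",
    "RuleCheck",
    "VerificationReport",
    "filter_by_score_and_presence",
    "verify_diagnostic_ions",
    "run_verification",
    "surrogate_score",
    "read_mgf",
    "read_ids_tsv",
    "MissingSpectrumError",
]


class MissingSpectrumError(KeyError):
    """An identification references a spectrum that cannot be resolved."""


@dataclass(frozen=True)
class ToleranceConfig:
    """Fragment-ion matching tolerance.

    ``mode="ppm"`` matches within ``tol_ppm`` parts per million with an
    absolute floor of ``abs_floor_da`` (ppm windows at low m/z would
    otherwise be narrower than instrument calibration supports);
    ``mode="da"`` uses a flat ``tol_da`` window.
    """

    mode: str = "ppm"
    tol_ppm: float = 30.0
    abs_floor_da: float = 0.01
    tol_da: float = 0.02

    def window(self, theoretical: float) -> float:
        if self.mode == "ppm":
            return max(theoretical * self.tol_ppm * 1e-6, self.abs_floor_da)
        if self.mode == "da":
            return self.tol_da
        raise ValueError(f"unknown tolerance mode {self.mode!r}")


@dataclass(frozen=True)
class Ms2Spectrum:
    """A fragment spectrum: precursor plus (m/z, intensity) peak list."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]
    sample_id: str = ""
    injection_id: int = 1

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        mzs = [mz for mz, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    def nearest_peak(self, mz: float) -> tuple[float, float] | None:
        """The peak closest in m/z, or None for an empty spectrum."""
        if not self.peaks:
            return None
        mzs = [p[0] for p in self.peaks]
        i = bisect_left(mzs, mz)
        best = min(
            (j for j in (i - 1, i) if 0 <= j < len(mzs)),
            key=lambda j: abs(mzs[j] - mz),
        )
        return self.peaks[best]


@dataclass(frozen=True)
class IdentifiedGlycopeptide:
    """One glycopeptide-spectrum match awaiting verification."""

    sample_id: str
    injection_id: int
    peptide: PeptideCandidate
    comp: GlycanComposition
    score: float
    spectrum_id: str
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")
        if not find_sequons(self.peptide):
            raise ValueError(
                f"peptide {self.peptide.sequence!r} carries no N-glycosylation sequon"
            )

    @property
    def glycoform_key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.peptide.sequence, str(self.comp))


@dataclass(frozen=True)
class RuleCheck:
    """Outcome of one required-ion check inside a verification rule."""

    rule: str
    required_mz: float
    matched_mz: float | None
    ppm_error: float | None
    charge: int = 1
    passed: bool = False


@dataclass(frozen=True)
class VerificationReport:
    verdict: bool
    rules_checked: tuple[RuleCheck, ...]

    @property
    def failed_rules(self) -> tuple[str, ...]:
        return tuple(sorted({c.rule for c in self.rules_checked if not c.passed}))


def _match_ion(
    spectrum: Ms2Spectrum, theoretical: float, tol: ToleranceConfig
) -> tuple[float, float] | tuple[None, None]:
    """(matched m/z, ppm error) of the closest peak within tolerance."""
    peak = spectrum.nearest_peak(theoretical)
    if peak is None or abs(peak[0] - theoretical) > tol.window(theoretical):
        return None, None
    return peak[0], (peak[0] - theoretical) / theoretical * 1e6


def verify_diagnostic_ions(
    gp: IdentifiedGlycopeptide,
    spectrum: Ms2Spectrum,
    tol: ToleranceConfig | None = None,
    y1_allow_charge2: bool = True,
) -> VerificationReport:
    """Check every diagnostic-ion rule applicable to ``gp`` against its spectrum.

    Rules, in order: Y1 always; a fucose ion (core Y1+Fuc OR antenna 512.20)
    if the composition is fucosylated; the Neu5Gc oxonium pair (290.09 AND
    308.10) if Neu5Gc-sialylated; the Neu5Ac pair (274.09 AND 292.10) if
    Neu5Ac-sialylated. Verdict passes iff all applicable rules matched.

    Y1 (and Y1+Fuc) are additionally searched doubly charged when the
    precursor charge is >= 2, since large Y ions commonly retain two protons;
    the matched charge state is recorded in the report.
    """
    if spectrum.spectrum_id != gp.spectrum_id:
        raise MissingSpectrumError(
            f"spectrum {spectrum.spectrum_id!r} does not match id {gp.spectrum_id!r}"
        )
    tol = tol or ToleranceConfig()
    pep_mass = masscalc.peptide_mass(
        gp.peptide.sequence, masscalc.ModificationSet.default()
    )
    checks: list[RuleCheck] = []

    def check_pep_ion(rule: str, mz1: float) -> RuleCheck:
        """Match a peptide-containing ion at charge 1, then 2 if allowed."""
        charges = [1]
        if y1_allow_charge2 and spectrum.precursor_charge >= 2:
            charges.append(2)
        for z in charges:
            mz = (mz1 - masscalc.PROTON + z * masscalc.PROTON) / z
            matched, err = _match_ion(spectrum, mz, tol)
            if matched is not None:
                return RuleCheck(rule, mz, matched, err, charge=z, passed=True)
        return RuleCheck(rule, mz1, None, None, passed=False)

    def check_small_ion(rule: str, mz: float) -> RuleCheck:
        matched, err = _match_ion(spectrum, mz, tol)
        return RuleCheck(rule, mz, matched, err, passed=matched is not None)

    y1_mz = masscalc.diagnostic_ion_mz("Y1", pep_mass)
    checks.append(check_pep_ion("Y1", y1_mz))

    if gp.comp.fuc > 0:
        core = check_pep_ion("fucose", masscalc.diagnostic_ion_mz("Y1_fuc", pep_mass))
        if core.passed:
            checks.append(core)
        else:
            antenna = check_small_ion(
                "fucose", masscalc.diagnostic_ion_mz("antenna_fuc")
            )
            checks.append(antenna if antenna.passed else core)

    if gp.comp.neu5gc > 0:
        checks.append(
            check_small_ion(
                "neu5gc_pair",
                masscalc.diagnostic_ion_mz("neu5gc_oxonium_minus_water"),
            )
        )
        checks.append(
            check_small_ion("neu5gc_pair", masscalc.diagnostic_ion_mz("neu5gc_oxonium"))
        )
    if gp.comp.neu5ac > 0:
        checks.append(
            check_small_ion(
                "neu5ac_pair",
                masscalc.diagnostic_ion_mz("neu5ac_oxonium_minus_water"),
            )
        )
        checks.append(
            check_small_ion("neu5ac_pair", masscalc.diagnostic_ion_mz("neu5ac_oxonium"))
        )

    return VerificationReport(
        verdict=all(c.passed for c in checks), rules_checked=tuple(checks)
    )


def filter_by_score_and_presence(
    ids: Sequence[IdentifiedGlycopeptide],
    threshold: float = 300.0,
    min_injections: int = 1,
) -> list[IdentifiedGlycopeptide]:
    """Retain glycoforms scoring above ``threshold`` (strictly) in at least
    ``min_injections`` distinct injections of their sample.

    All observations of a retained glycoform are kept — the presence filter
    gates identification confidence, not quantitation coverage.
    """
    if min_injections < 1:
        raise ValueError("min_injections must be >= 1")
    qualifying: dict[tuple, set[int]] = {}
    for gp in ids:
        if gp.score > threshold:
            qualifying.setdefault(gp.glycoform_key, set()).add(gp.injection_id)
    retained = {k for k, inj in qualifying.items() if len(inj) >= min_injections}
    return [gp for gp in ids if gp.glycoform_key in retained]


def run_verification(
    ids: Sequence[IdentifiedGlycopeptide],
    spectra: Mapping[str, Ms2Spectrum] | Iterable[Ms2Spectrum],
    tol: ToleranceConfig | None = None,
    score_min: float = 300.0,
    min_injections: int = 1,
    y1_allow_charge2: bool = True,
    audit_path: str | Path | None = None,
) -> tuple[list[IdentifiedGlycopeptide], list[dict]]:
    """Full acceptance pipeline: diagnostic-ion verification, then the
    score/presence filter on the survivors.

    Returns the accepted identifications (canonically sorted, so the result
    is independent of input order) and an audit log with one record per
    rejected identification and per dangling spectrum reference. The audit
    log is additionally written as JSON-lines when ``audit_path`` is given.
    """
    if not isinstance(spectra, Mapping):
        spectra = {s.spectrum_id: s for s in spectra}
    audit: list[dict] = []
    survivors: list[IdentifiedGlycopeptide] = []
    for gp in sorted(ids, key=lambda g: (g.glycoform_key, g.injection_id, g.spectrum_id)):
        spec = spectra.get(gp.spectrum_id)
        if spec is None:
            audit.append(
                {
                    "spectrum_id": gp.spectrum_id,
                    "glycoform": gp.glycoform_key,
                    "injection": gp.injection_id,
                    "reason": "missing_spectrum",
                }
            )
            continue
        report = verify_diagnostic_ions(gp, spec, tol, y1_allow_charge2)
        if report.verdict:
            survivors.append(gp)
        else:
            audit.append(
                {
                    "spectrum_id": gp.spectrum_id,
                    "glycoform": gp.glycoform_key,
                    "injection": gp.injection_id,
                    "reason": "diagnostic_ion",
                    "failed_rules": list(report.failed_rules),
                    "rules": [asdict(c) for c in report.rules_checked],
                }
            )
    accepted = filter_by_score_and_presence(survivors, score_min, min_injections)
    dropped = {g.glycoform_key for g in survivors} - {g.glycoform_key for g in accepted}
    for key in sorted(dropped):
        audit.append({"glycoform": key, "reason": "score_or_presence"})
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            for rec in audit:
                fh.write(json.dumps(rec, default=str) + "\n")
    return accepted, audit


def surrogate_score(
    gp_peptide: str,
    comp: GlycanComposition,
    spectrum: Ms2Spectrum,
    tol: ToleranceConfig | None = None,
    mods: masscalc.ModificationSet | None = None,
) -> float:
    """Identification score from the glycan Y-ion ladder.

    The theoretical ladder is the bare peptide plus successively larger
    glycan stubs (peptide, +HexNAc, +HexNAc2, +HexNAc2Hex1..3, +Fuc variants
    where applicable), singly and doubly protonated. Each theoretical ion
    matched within tolerance contributes ``-log10(max(|ppm error|, 0.1))
    + 1`` — close matches count more, and 0.1 ppm is the floor below which
    mass accuracy is not rewarded further.
    """
    tol = tol or ToleranceConfig()
    mods = mods or masscalc.ModificationSet.default()
    pep = masscalc.peptide_mass(gp_peptide, mods)
    stubs = [0.0]
    acc = 0.0
    for sugar, n in (("HexNAc", min(comp.hexnac, 2)), ("Hex", min(comp.hex, 3))):
        for _ in range(n):
            acc += masscalc._DEFAULT_SUGARS[sugar]
            stubs.append(acc)
    if comp.fuc:
        stubs.extend(s + masscalc._DEFAULT_SUGARS["Fuc"] for s in list(stubs))
    score = 0.0
    seen: set[float] = set()
    for stub in stubs:
        for z in (1, 2):
            mz = (pep + stub + z * masscalc.PROTON) / z
            matched, err = _match_ion(spectrum, mz, tol)
            if matched is not None and matched not in seen:
                seen.add(matched)
                score += -np.log10(max(abs(err), 0.1)) + 1.0
    return float(score)


# ---------------------------------------------------------------------------
# I/O


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read an MGF peak list. TITLE carries the spectrum id; optional
    SAMPLE/INJECTION params are honoured if present."""
    from pyteomics import mgf

    out = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params.get("charge", [1])[0])
            out.append(
                Ms2Spectrum(
                    spectrum_id=str(params.get("title", "")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=max(charge, 1),
                    peaks=tuple(
                        zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
                    ),
                    sample_id=str(params.get("sample", "")),
                    injection_id=int(params.get("injection", 1)),
                )
            )
    return out


def read_ids_tsv(path: str | Path) -> list[IdentifiedGlycopeptide]:
    """Read identifications from TSV with columns: sample, injection, peptide,
    composition, score, spectrum_id and optionally intensity (native export
    and Byonic-like exports share this layout)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        seq = str(row.peptide)
        out.append(
            IdentifiedGlycopeptide(
                sample_id=str(row.sample),
                injection_id=int(row.injection),
                peptide=PeptideCandidate(
                    sequence=seq,
                    start=0,
                    end=len(seq),
                    missed_cleavages=0,
                    sequon_positions=find_sequons(seq),
                ),
                comp=parse_composition(str(row.composition)),
                score=float(row.score),
                spectrum_id=str(row.spectrum_id),
                intensity=float(getattr(row, "intensity", 0.0)),
            )
        )
    return out
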