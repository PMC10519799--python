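"""Synthetic glycoproteomics study generator.

Emulates the structure of a murine IgG-Fc glycosylation experiment: per
mouse, three replicate LC-MS/MS injections of the tryptic glycopeptide
EDYNSTIR (IgG2b), each glycoform observed as one precursor feature with a
log-normally perturbed intensity and one MS2 spectrum carrying the
diagnostic ions (Y1, core-fucose Y1+Fuc, sialic oxonium pairs) at their
theoretical m/z within a small instrument jitter, plus uniform noise peaks.
Group structure shifts the glycoform distribution — by default a
placebo-like G0-dominant profile against a treated profile with mass moved
from G0 into the sialylated (GS) forms.

Everything is driven by one RNG seed: the same seed reproduces the outputs
byte for byte. Ground truth (per-mouse glycoform proportions, per-readout
group means) is stored alongside the outputs so recovery can be tested.

The generator makes no attempt to mimic chromatography, isotope envelopes,
co-isolation or Byonic's scoring; identification scores are drawn from a
configured normal distribution, and features are never missing unless ion
deletion or score configuration makes them fail downstream filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import masscalc
from .digestion import PeptideCandidate, find_sequons
from .glycospace import parse_composition
from .verify import IdentifiedGlycopeptide, Ms2Spectrum

__all__ = [
    "IonDeletion",
    "SimulationConfig",
    "ElisaGroupConfig",
    "SimulationResult",
    "default_proportions",
    "shifted_proportions",
    "simulate_study",
    "simulate_elisa_readouts",
    "ids_from_features",
    "write_mgf",
]

#: Placebo-like glycoform profile on the biantennary Neu5Gc space
#: (G0-dominant, ~12% sialylated), loosely shaped like an estrogen-deficient
#: mouse but synthetic by construction, not fitted to any measured data.
_DEFAULT_PROPS = {
    "HexNAc(4)Hex(3)Fuc(1)": 0.52,  # G0F
    "HexNAc(4)Hex(3)": 0.06,  # G0
    "HexNAc(4)Hex(4)Fuc(1)": 0.20,  # G1F
    "HexNAc(4)Hex(5)Fuc(1)": 0.10,  # G2F
    "HexNAc(4)Hex(5)Fuc(1)NeuGc(1)": 0.08,  # G2FS1
    "HexNAc(4)Hex(5)Fuc(1)NeuGc(2)": 0.04,  # G2FS2
}


def default_proportions() -> dict[str, float]:
    return dict(_DEFAULT_PROPS)


def shifted_proportions(
    base: Mapping[str, float] | None = None, gs_shift: float = 0.08
) -> dict[str, float]:
    """Move ``gs_shift`` probability mass from the agalacto (G0) forms into
    the sialylated forms, pro rata — the treated-group contrast."""
    base = dict(base or _DEFAULT_PROPS)
    sial = {c for c in base if parse_composition(c).sialic > 0}
    agal = {c for c in base if parse_composition(c).hex <= 3}
    if not sial or not agal:
        raise ValueError("base profile needs both sialylated and G0 forms")
    w_s = sum(base[c] for c in sial)
    w_a = sum(base[c] for c in agal)
    if gs_shift >= w_a:
        raise ValueError("shift exceeds available G0 mass")
    out = dict(base)
    for c in sial:
        out[c] += gs_shift * base[c] / w_s
    for c in agal:
        out[c] -= gs_shift * base[c] / w_a
    return out


@dataclass(frozen=True)
class IonDeletion:
    """Negative-control spec: strip one diagnostic ion kind from spectra.

    ``kind`` is a diagnostic-ion kind (:data:`masscalc.DIAGNOSTIC_ION_KINDS`);
    ``selector`` restricts the targeted spectra — "all", a composition trait
    ("neu5ac", "neu5gc", "fuc"), or an exact composition string.
    """

    kind: str
    selector: str = "all"

    def applies_to(self, composition: str) -> bool:
        if self.selector == "all":
            return True
        comp = parse_composition(composition)
        if self.selector == "neu5ac":
            return comp.neu5ac > 0
        if self.selector == "neu5gc":
            return comp.neu5gc > 0
        if self.selector == "fuc":
            return comp.fuc > 0
        return self.selector == composition


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic glycoproteomics experiment.

    Defaults emulate the two-group estrogen-treatment contrast: 5 mice per
    group, 3 injections each, a G0-dominant placebo profile and a treated
    profile with 8 percentage points moved into the sialylated forms.
    """

    group_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "OVX-Pla": default_proportions(),
            "OVX-E2": shifted_proportions(gs_shift=0.08),
        }
    )
    n_mice: int = 5
    n_injections: int = 3
    peptide: str = "EDYNSTIR"
    intensity_scale: float = 1.0e6
    lognormal_sd: float = 0.25
    mouse_concentration: float | None = 150.0  # Dirichlet; None = no mouse effect
    jitter_ppm: float = 5.0  # uniform +/- window on emitted fragment m/z
    emission_prob: float = 1.0
    ion_deletion: tuple[IonDeletion, ...] = ()
    n_noise_peaks: int = 20
    precursor_charge: int = 2
    score_mean: float = 450.0
    score_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if not (0.0 <= self.emission_prob <= 1.0):
            raise ValueError("emission_prob must lie in [0, 1]")
        for grp, props in self.group_proportions.items():
            tot = sum(props.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"proportions for group {grp!r} sum to {tot}, not 1"
                )
            if any(p < 0 for p in props.values()):
                raise ValueError(f"negative proportion in group {grp!r}")


@dataclass
class SimulationResult:
    spectra: list[Ms2Spectrum]
    features: pd.DataFrame
    design: pd.DataFrame
    truth: dict


def _diagnostic_peaks(
    comp_str: str, pep_mass: float, rng: np.random.Generator, cfg: SimulationConfig
) -> list[tuple[str, float, float]]:
    """(ion kind, theoretical m/z, intensity) for every applicable ion."""
    comp = parse_composition(comp_str)
    ions: list[tuple[str, float, float]] = []

    def add(kind: str, mz: float, inten: float) -> None:
        ions.append((kind, mz, inten))

    add("Y1", masscalc.diagnostic_ion_mz("Y1", pep_mass), 8000.0)
    # Y-ladder stubs for the surrogate score (bare peptide, +HexNAc2, +Hex1-3)
    stub = pep_mass
    add("y0", stub + masscalc.PROTON, 3000.0)
    for sugar in ("HexNAc", "Hex", "Hex", "Hex"):
        stub += masscalc._DEFAULT_SUGARS[sugar]
        add("ladder", stub + masscalc.PROTON, 2500.0)
    if comp.fuc > 0:
        add("Y1_fuc", masscalc.diagnostic_ion_mz("Y1_fuc", pep_mass), 5000.0)
        add("antenna_fuc", masscalc.diagnostic_ion_mz("antenna_fuc"), 1500.0)
    if comp.neu5gc > 0:
        add("neu5gc_oxonium", masscalc.diagnostic_ion_mz("neu5gc_oxonium"), 6000.0)
        add(
            "neu5gc_oxonium_minus_water",
            masscalc.diagnostic_ion_mz("neu5gc_oxonium_minus_water"),
            4000.0,
        )
    if comp.neu5ac > 0:
        add("neu5ac_oxonium", masscalc.diagnostic_ion_mz("neu5ac_oxonium"), 6000.0)
        add(
            "neu5ac_oxonium_minus_water",
            masscalc.diagnostic_ion_mz("neu5ac_oxonium_minus_water"),
            4000.0,
        )
    return ions


def simulate_study(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SimulationResult:
    """Generate the full synthetic study.

    Returns in-memory spectra, a feature table, a design table and the
    ground truth; when ``out_dir`` is given, additionally writes one MGF per
    sample-injection, ``features.tsv``, ``design.csv`` and ``truth.json``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    pep_mass = masscalc.peptide_mass(cfg.peptide, masscalc.ModificationSet.default())

    spectra: list[Ms2Spectrum] = []
    feat_rows: list[dict] = []
    design_rows: list[dict] = []
    truth_mice: dict[str, dict] = {}

    for group in cfg.group_proportions:
        props = cfg.group_proportions[group]
        comps = sorted(props)
        p_group = np.array([props[c] for c in comps])
        for m in range(1, cfg.n_mice + 1):
            sample = f"{group}-m{m:02d}"
            if cfg.mouse_concentration is None:
                p_mouse = p_group.copy()
            else:
                p_mouse = rng.dirichlet(cfg.mouse_concentration * p_group)
            truth_mice[sample] = {
                "group": group,
                "proportions": dict(zip(comps, p_mouse.tolist())),
            }
            design_rows.append({"mouse": sample, "group": group})
            for inj in range(1, cfg.n_injections + 1):
                noise = rng.normal(0.0, cfg.lognormal_sd, size=len(comps))
                intensities = cfg.intensity_scale * p_mouse * np.exp(noise)
                for comp_str, inten in zip(comps, intensities):
                    spec_id = f"{sample}_inj{inj}_{comp_str}"
                    peaks = []
                    for kind, mz, base_inten in _diagnostic_peaks(
                        comp_str, pep_mass, rng, cfg
                    ):
                        deleted = any(
                            d.kind == kind and d.applies_to(comp_str)
                            for d in cfg.ion_deletion
                        )
                        emit = cfg.emission_prob >= 1.0 or (
                            rng.random() < cfg.emission_prob
                        )
                        if deleted or not emit:
                            continue
                        jitter = rng.uniform(-cfg.jitter_ppm, cfg.jitter_ppm)
                        peaks.append(
                            (mz * (1.0 + jitter * 1e-6), base_inten * rng.uniform(0.5, 1.5))
                        )
                    noise_mz = rng.uniform(200.0, 2000.0, size=cfg.n_noise_peaks)
                    noise_int = rng.uniform(10.0, 200.0, size=cfg.n_noise_peaks)
                    peaks.extend(zip(noise_mz.tolist(), noise_int.tolist()))
                    glycan = parse_composition(comp_str)
                    prec = masscalc.precursor_mz(
                        pep_mass, masscalc.glycan_mass(glycan), cfg.precursor_charge
                    )
                    spectra.append(
                        Ms2Spectrum(
                            spectrum_id=spec_id,
                            precursor_mz=prec,
                            precursor_charge=cfg.precursor_charge,
                            peaks=tuple(sorted(peaks)),
                            sample_id=sample,
                            injection_id=inj,
                        )
                    )
                    feat_rows.append(
                        {
                            "sample": sample,
                            "injection": inj,
                            "peptide": cfg.peptide,
                            "composition": comp_str,
                            "intensity": float(inten),
                            "charge": cfg.precursor_charge,
                            "score": max(float(rng.normal(cfg.score_mean, cfg.score_sd)), 1.0),
                            "spectrum_id": spec_id,
                        }
                    )

    features = pd.DataFrame(feat_rows)
    design = pd.DataFrame(design_rows)
    truth = {
        "group_proportions": {
            g: dict(p) for g, p in cfg.group_proportions.items()
        },
        "mice": truth_mice,
        "gs_true": {
            s: sum(
                p
                for c, p in info["proportions"].items()
                if parse_composition(c).sialic > 0
            )
            for s, info in truth_mice.items()
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        by_run: dict[tuple[str, int], list[Ms2Spectrum]] = {}
        for s in spectra:
            by_run.setdefault((s.sample_id, s.injection_id), []).append(s)
        for (sample, inj), specs in sorted(by_run.items()):
            write_mgf(specs, out / f"{sample}_inj{inj}.mgf")
        features.to_csv(out / "features.tsv", sep="\t", index=False)
        design.to_csv(out / "design.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return SimulationResult(spectra, features, design, truth)


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed numeric formatting (seed-stable bytes)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            fh.write(f"SAMPLE={s.sample_id}\n")
            fh.write(f"INJECTION={s.injection_id}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


def ids_from_features(
    features: pd.DataFrame, peptide_col: str = "peptide"
) -> list[IdentifiedGlycopeptide]:
    """Lift a feature table into identifications for the verification stage."""
    out = []
    for row in features.itertuples(index=False):
        seq = getattr(row, peptide_col)
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
                intensity=float(row.intensity),
            )
        )
    return out


@dataclass(frozen=True)
class ElisaGroupConfig:
    """Per-group Gaussian readout parameters: readout -> (mean, sd)."""

    readouts: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (mu, sd) in self.readouts.items():
            if mu < 0:
                raise ValueError(f"negative configured mean for {name!r}")
            if sd < 0:
                raise ValueError(f"negative sd for {name!r}")


def simulate_elisa_readouts(
    groups: Mapping[str, ElisaGroupConfig],
    n_per_group: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Immunoassay-style per-mouse readouts (total IgG, IgM, sialic
    acid/protein ...): independent Gaussian draws per group, truncated at 0.

    Returns a tidy design table (mouse, group, readout, value) and the truth
    (configured group means).
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for group in groups:
        cfg = groups[group]
        truth[group] = {k: mu for k, (mu, _) in cfg.readouts.items()}
        for m in range(1, n_per_group + 1):
            mouse = f"{group}-m{m:02d}"
            for readout, (mu, sd) in cfg.readouts.items():
                if sd == 0:
                    val = mu
                else:
                    a = (0.0 - mu) / sd  # truncate at zero
                    val = float(
                        sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
                    )
                rows.append(
                    {"mouse": mouse, "group": group, "readout": readout, "value": val}
                )
    return pd.DataFrame(rows), truth
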