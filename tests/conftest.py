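import pytest

from glycoforms import masscalc, synthetic
from glycoforms.digestion import PeptideCandidate, find_sequons
from glycoforms.glycospace import parse_composition
from glycoforms.verify import IdentifiedGlycopeptide, Ms2Spectrum


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic study (2 groups x 5 mice x 3 injections)."""
    return synthetic.simulate_study(synthetic.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def edynstir_mass():
    return masscalc.peptide_mass("EDYNSTIR", masscalc.ModificationSet.default())


def make_candidate(seq: str) -> PeptideCandidate:
    return PeptideCandidate(
        sequence=seq,
        start=0,
        end=len(seq),
        missed_cleavages=0,
        sequon_positions=find_sequons(seq),
    )


def make_spectrum(
    peptide: str,
    comp_str: str,
    spectrum_id: str = "s1",
    drop_ions: tuple[str, ...] = (),
    extra_peaks: tuple[tuple[float, float], ...] = (),
    charge: int = 2,
) -> tuple[IdentifiedGlycopeptide, Ms2Spectrum]:
    """A hand-built clean identification/spectrum pair with every applicable
    diagnostic ion at exact theoretical m/z (minus any in ``drop_ions``)."""
    comp = parse_composition(comp_str)
    pep_mass = masscalc.peptide_mass(peptide, masscalc.ModificationSet.default())
    ions = {"Y1": masscalc.diagnostic_ion_mz("Y1", pep_mass)}
    if comp.fuc:
        ions["Y1_fuc"] = masscalc.diagnostic_ion_mz("Y1_fuc", pep_mass)
    if comp.neu5gc:
        ions["neu5gc_oxonium"] = masscalc.diagnostic_ion_mz("neu5gc_oxonium")
        ions["neu5gc_oxonium_minus_water"] = masscalc.diagnostic_ion_mz(
            "neu5gc_oxonium_minus_water"
        )
    if comp.neu5ac:
        ions["neu5ac_oxonium"] = masscalc.diagnostic_ion_mz("neu5ac_oxonium")
        ions["neu5ac_oxonium_minus_water"] = masscalc.diagnostic_ion_mz(
            "neu5ac_oxonium_minus_water"
        )
    peaks = [(mz, 1000.0) for k, mz in ions.items() if k not in drop_ions]
    peaks.extend(extra_peaks)
    spectrum = Ms2Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=masscalc.precursor_mz(pep_mass, masscalc.glycan_mass(comp), charge),
        precursor_charge=charge,
        peaks=tuple(sorted(peaks)),
    )
    gp = IdentifiedGlycopeptide(
        sample_id="s",
        injection_id=1,
        peptide=make_candidate(peptide),
        comp=comp,
        score=400.0,
        spectrum_id=spectrum_id,
    )
    return gp, spectrum
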