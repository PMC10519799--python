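"""Masses of the IgG2b Fc glycopeptide EDYNSTIR and its diagnostic ions.

Computes the neutral peptide and glycan masses, the observable precursor m/z
at charges 2-3, and the reporter ions used to verify glycopeptide identity.
"""

from glycoforms import masscalc as mc
from glycoforms.glycospace import parse_composition

peptide = "EDYNSTIR"
pep_mass = mc.peptide_mass(peptide, mc.ModificationSet.default())
g0f = parse_composition("HexNAc(4)Hex(3)Fuc(1)")
gly_mass = mc.glycan_mass(g0f)

print(f"peptide {peptide}: {pep_mass:.4f} Da")
print(f"glycan G0F {g0f}: {gly_mass:.4f} Da")
for z in (2, 3):
    print(f"precursor [M+{z}H]{z}+: m/z {mc.precursor_mz(pep_mass, gly_mass, z):.4f}")

print("\ndiagnostic ions (singly protonated):")
for kind in mc.DIAGNOSTIC_ION_KINDS:
    mz = mc.diagnostic_ion_mz(kind, pep_mass)
    print(f"  {kind:28s} m/z {mz:9.4f}  (~{round(mz)})")

# A spectrum peak matches a theoretical ion when its relative error is
# within the MS2 tolerance (30 ppm by default).
print("\n292.1040 vs Neu5Ac oxonium at 30 ppm:",
      mc.ppm_match(292.1040, mc.diagnostic_ion_mz("neu5ac_oxonium"), 30))
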