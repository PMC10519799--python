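"""Enumerate the biantennary complex glycan space and label each glycoform.

The G0/G1/G2 label counts terminal galactoses, S1/S2 the sialic acids;
fucosylation and bisection are carried as flags.
"""

from glycoforms.glycospace import enumerate_biantennary, label_glycoform
from glycoforms.masscalc import glycan_mass

comps = enumerate_biantennary(max_sialic=2, allow_fuc=True, allow_bisect=False,
                              sialic_kind="neu5gc")
print(f"{len(comps)} biantennary compositions (<=2 Neu5Gc, core fucose on/off):\n")
for c in comps:
    print(f"  {str(c):34s} {label_glycoform(c).name:7s} {glycan_mass(c):9.4f} Da")
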