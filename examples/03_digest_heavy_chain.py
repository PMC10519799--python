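"""Tryptic digestion of an IgG2b heavy-chain fragment with sequon detection.

Cleaves after K/R with up to two missed cleavages and reports every peptide
carrying an N-glycosylation sequon (N-X-S/T, X != P) — the candidates that
can carry the Fc N-glycan.
"""

from glycoforms.digestion import tryptic_digest

# murine IgG2b CH2-region fragment containing the conserved glycosylation site
FRAGMENT = (
    "PNLEGGPSVFIFPPNIKDVLMISLTPKVTCVVVDVSEDDPDVQISWFVNNVEVHTAQTQTHREDYNSTIR"
    "VVSTLPIQHQDWMSGKEFKCK"
)

candidates = tryptic_digest(FRAGMENT, max_missed=2)
print(f"{len(candidates)} tryptic peptides (<=2 missed cleavages)")
print("\nsequon-bearing candidates:")
for c in candidates:
    if c.sequon_positions:
        print(f"  {c.sequence:30s} missed={c.missed_cleavages} "
              f"sequon at peptide position {c.sequon_positions}")
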