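# Methods

## Scope and model

The package models the computational half of a label-free IgG-Fc
N-glycosylation study in mice: glycopeptide identification support,
fragment-level verification, precursor-intensity relative quantitation, and
the group statistics of a two- or three-arm animal experiment. Everything
upstream of the peak lists (chromatography, feature detection, raw-file
handling) is out of scope: spectra arrive as MGF peak lists and quantitative
inputs as per-feature intensities.

## Mass arithmetic (`masscalc`)

All masses are monoisotopic. The built-in residue table covers the 20
standard amino acids; water is 18.010565 Da and the proton 1.007276 Da (a
1.0 Da proton would already be off by ~7000 ppm at m/z 290, far outside the
30 ppm matching window, so the physical proton mass is non-negotiable).
Monosaccharide residue masses: HexNAc 203.079373, Hex 162.052824, Fuc
146.057909, Neu5Ac 291.095417, Neu5Gc 307.090331 Da. Fixed modifications
(default: methylthio-Cys, +45.9877 Da) are applied by `peptide_mass`;
variable modifications (default: Met oxidation, +15.9949 Da, at most one per
peptide) are carried as metadata for candidate expansion rather than folded
into the base mass. Tables are versioned constants, overridable from
YAML/JSON.

Diagnostic-ion matching defaults to 30 ppm (the usual high-resolution MS2
tolerance) with an absolute floor of ±0.01 Da; a flat-Da mode exists because
published workflows do not always state which convention was used for
low-mass reporter ions. The ppm window is inclusive at the boundary.

## Glycan space (`glycospace`)

Complex biantennary N-glycans are enumerated structurally: core
HexNAc₂Hex₃, two GlcNAc antennae, each optionally extended with galactose
and then sialic acid (so sialic ≤ galactose ≤ 2), optional core fucose
(0–1) and optional bisecting GlcNAc (0–1, folded into the HexNAc count
because composition-level MS cannot distinguish the isomer). Sialic acids
are Neu5Ac or Neu5Gc but never mixed on one glycan by default — the common
database convention — exposed as `sialic_kind`. Oligomannose (Man5–Man9)
and simple hybrid forms are enumerable behind flags but are labelled
`other` and excluded from trait summaries, which are defined only for
complex biantennary forms. Canonical ordering is lexicographic on
(HexNAc, Hex, Fuc, sialic) so outputs are reproducible. Compositions
serialize to Byonic-style strings (`HexNAc(4)Hex(5)Fuc(1)NeuGc(2)`) and
round-trip through the parser; the bisecting flag is intentionally not
encoded in the string.

We make no claim to reproduce any particular commercial glycan database's
membership or size; the enumerator is constraint-driven.

## Digestion (`digestion`)

Trypsin is modelled as cleavage after K/R with up to `max_missed` (default
2) missed cleavages. Proline suppression (no cleavage before P) is off by
default and available as a flag, since search engines are commonly
configured with the plain rule. Coordinates are 0-based half-open;
sequons are N-X-S/T with X ≠ P, reported at peptide-local indices, and a
motif truncated by the peptide boundary is not reported (it cannot be
glycosylated evidence within that peptide).

## Verification (`verify`)

The acceptance filter is a deterministic rule engine replacing manual
spectrum checking. Rules, in order: Y1 always; fucose evidence (core
Y1+Fuc or antenna m/z 512.1974) if the composition carries fucose; the
Neu5Gc oxonium pair 290.0870/308.0976 if Neu5Gc is present; the Neu5Ac
pair 274.0921/292.1027 if Neu5Ac is present. A hit passes iff every
applicable rule matches; the report lists every checked ion with the
matched peak and its ppm error, and the run-level audit log (JSON-lines)
records each rejection with the violated rule. Peptide-containing ions (Y1,
Y1+Fuc) are additionally searched doubly protonated when the precursor
charge is ≥ 2, with the matched charge recorded — large Y ions frequently
retain two charges.

The score/presence filter retains a (sample, peptide, composition)
glycoform if it scored strictly above the threshold in at least
`min_injections` (default 1) distinct injections; all observations of a
retained glycoform are kept for quantitation. Importable search-engine
scores use their native scale (300 is the conventional Byonic cutoff). For
in-house identifications `surrogate_score` counts matched glycan Y-ladder
peaks weighted by −log10(|ppm error|, floored at 0.1 ppm) + 1; this scale
is documented as not comparable to any commercial score, and the threshold
must be configured per score source.

Filter composition: diagnostic-ion verification runs first, then the
score/presence filter on the survivors, so an injection whose spectrum
fails verification cannot contribute presence evidence. Missing spectra are
enumerated in the audit log and the run continues.

## Quantitation (`quant`)

Within each (sample, injection, peptide), accepted-glycoform intensities
are normalised to percentages (charge states/duplicate features summed
first); the per-sample value is the mean over injections in which the
peptide was detected. A glycoform absent from one injection counts as 0%
there when the peptide itself was detected (the identified set defines the
denominator per injection); `missing_policy="available"` switches to
averaging only over the injections where the glycoform was observed. An
injection with zero total intensity is excluded from the mean with a
warning. Quantitation is restricted to one peptide backbone — by default
the one with the greatest summed intensity across the sample set,
reflecting reporting on the dominant IgG subtype — overridable via the
`peptide` argument.

Trait summaries: G0 (agalactosylated, any fucosylation/bisection), G1/G2
(galactosylated asialo), GS (all sialylated forms), `other`
(non-biantennary); these four partition 100% within numerical tolerance.
Fucosylated percent is reported alongside and overlaps the partition.

## Statistics (`stats`)

* **Grubbs.** Two-sided, critical value
  G = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student quantile at
  n−2 df. Default is iterative removal (one value per round, to
  exhaustion); `max_rounds=1` gives the single-pass variant, since sources
  rarely state which was used. n < 3 skips the test with a warning;
  zero-variance input removes nothing.
* **Dunnett.** Adjusted p = P(max₁..k |Tᵢ| > |t_obs|) under the joint null
  of the many-to-one t statistics sharing the pooled scale (χ_ν/√ν) and
  reference mean. Conditioning on both, the comparisons are independent
  normals; the resulting double integral is evaluated with 80-node
  Gauss–Hermite quadrature (shared-mean dimension) and adaptive quadrature
  (scale dimension), accurate to ~1e-8 — with one comparison it reduces to
  the Student t tail, and it handles unbalanced designs through the
  per-comparison standard errors. A seeded Monte-Carlo evaluator of the
  same probability serves as an independent cross-check (tests require
  agreement within ~1e-3 at 10⁵ draws).
* **t-test.** Pooled-variance Student by default, Welch behind a flag;
  degenerate variances with equal means yield p = 1 with a warning.
* **Power.** Two-sample two-sided power via the noncentral t with
  noncentrality d·√(n/2) and df 2n−2; `sample_size_t` returns the smallest
  n reaching target power (matching the standard power-software t-family
  computation; e.g. d = 1.66, α = 0.05, power 0.80 → n = 7, and
  d = 0.5 → n = 64).
* **ddCT.** ΔCT = CT_target − CT_housekeeping per sample; expression is
  2^−(ΔCT − c)·100 with c the arithmetic mean ΔCT of the reference group
  (median behind `center="median"`). Note the mean of the outputs within
  the reference group is ≥ 100% by Jensen's inequality; only the
  geometric-scale centring is exactly 100%.
* **Driver.** `analyze_design` applies Grubbs per readout per group, then
  chooses ANOVA+Dunnett (≥ 3 groups) or Student's t (2 groups), emitting a
  tidy comparisons table and a JSON run report.

## Synthetic data (`synthetic`)

The generator emulates the structure of the real experiment: groups of mice
(default two groups × 5), three injections each, the EDYNSTIR backbone, and
a glycoform profile per group over the biantennary Neu5Gc space. Defaults:
a G0-dominant placebo profile (52% G0F, 6% G0, 20% G1F, 10% G2F, 8% G2FS1,
4% G2FS2; ~12% sialylated) and a treated profile with 8 percentage points
moved pro rata from the G0 into the sialylated forms — shaped like an
estrogen-treatment contrast but synthetic by construction, not fitted to
measured data. Per-mouse profiles are Dirichlet-perturbed around the group
vector (concentration 150, a mild biological variance; `None` disables).
Intensities are log-normal around scale × proportion with σ = 0.25
(a typical label-free CV); fragment m/z jitter is uniform ±5 ppm, well
inside the 30 ppm matching window, so clean data always verifies.
Identification scores are drawn N(450, 60²) — above the conventional 300
cutoff — rather than computed, keeping score filtering controllable.
Diagnostic-ion emission probability and a targeted ion-deletion spec
provide negative controls whose rejection set is known exactly. All
randomness flows from one seed; outputs (including MGF bytes, written with
fixed numeric formatting) are reproducible bit-for-bit.

What the generator does **not** emulate: chromatographic peak shape,
isotope envelopes, co-isolation/chimeric spectra, missing features,
between-injection batch effects, or realistic score distributions. Passing
tests therefore demonstrate the correctness of the pipeline's rules and
arithmetic on structurally faithful inputs, not robustness to every
instrument artefact.

## Problem sizes and numerical choices

Test and acceptance workloads are deliberately desk-scale: the default
study is 10 mice × 3 injections × 6 glycoforms (180 spectra), recovery
checks use 20 seeds of a 3-mouse study, the Dunnett Monte-Carlo cross-check
uses 10⁵ draws, and power calibration 5000 replicates — sizes at which all
Monte-Carlo tolerances quoted above are comfortably resolved. Percent
normalisation asserts conservation to 1e-6; mass assertions use 1e-3 Da
(hand-derived values are rounded to 4 decimals). Ties in dominant-peptide
selection break alphabetically; canonical sorting of accepted
identifications makes verification order-independent.

## Known limitations

No FDR/decoy machinery (none is modelled); no linkage/isomer inference; no
absolute quantitation; the surrogate score is a documented stand-in, not a
calibrated replacement for a search engine's score; Dunnett assumes equal
variances (as does the classical procedure); mixed-model or longitudinal
analyses of repeated serum timepoints are out of scope — each timepoint is
compared independently.
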