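# Methods

This note records the models, defaults, and design choices behind
`neosrm`, and what the bundled simulator does and does not emulate.

## Peptide chemistry

All masses are monoisotopic: SRM Q1/Q3 set points target the monoisotopic
species. Residue masses ship in `src/neosrm/data/aa_monoisotopic.tsv`
(6 decimal places, derived from standard isotope masses); the proton is
taken as 1.007276 Da and water as 18.010565 Da. `m/z = (M + z·1.007276)/z`.
Fragment series are restricted to b and y at product charge 1+ by default
(configurable), the triple-quadrupole CID convention; a/x/c/z ions are not
generated. Hydrophobicity is the Kyte–Doolittle GRAVY score
(`kyte_doolittle.tsv`).

Heavy standards follow the stable-isotope-label convention: a C-terminal
K or R carries +8.014199 / +10.008269 Da (fully ¹³C/¹⁵N-labelled residue).
HLA-eluted peptides are frequently non-tryptic, so no silent default exists
for other C termini — `heavy_peptide` demands an explicit label there, and
the benchmark fixtures use `isotope_label_shift`, which generalizes K+8/R+10
to any residue from its C/N atom counts. This label model is a declared
convention of the package, not a measured property of any vendor's
standards.

The size-exclusion gate retains peptides with 800 < M < 2000 Da, strict on
both sides: collection starts only after the 2000 Da ladder peak has eluted
and stops before the 800 Da peak, and SEC elutes large→small. A practical
consequence visible in the worked example: hydrophobic 8-mers (and the
784.5 Da KRAS G12V 9-mer) fall below the gate.

## Candidate enumeration

Coordinates are 1-based protein positions, matching `p.G12V` notation;
genomic coordinates never appear. For a site at position p in a protein of
length n, each length L ∈ {8..12} contributes
`min(p, n−L+1) − max(1, p−L+1) + 1` windows, giving the 50-candidate
ceiling exactly when ≥ 11 residues flank the site on both sides. Candidates
are enumerated on the mutated sequence and keyed by (start, length), so
repetitive contexts legitimately yield duplicate sequences at distinct
positions. Wild-type counterpart windows are available as optional controls
(off by default). Only missense substitutions are modelled; indels and
frameshifts are out of scope.

## Collision-energy optimization

The theoretical CE is a per-charge linear model
`CE = slope·(m/z) + intercept`, floored at 2 eV; defaults are
slope 0.031 / intercept 1.0 for 2+ and 0.036 / −4.8 for 3+, chosen as
concrete, editable values in the style of vendor CE equations and
overridable via the YAML config. Precursor charges default to 2+/3+, the
usual electrospray states of 8–12-mers.

Stage 1 measures each transition at {CE−5, CE, CE+5}; stage 2 at
{CE+2k, k = −4..4}. Grids are clamped at the 2 eV floor, which can merge
points for very low theoretical CEs; cardinalities are exactly 3 and 9
otherwise. "Highest abundance" is interpreted as the maximum intensity over
a transition's own grid; a trapezoidal area-under-the-curve score is
available behind a flag but is not the default. Every ranking uses a documented total order — intensity,
then higher product m/z, then y before b, then lower ordinal; CE ties go to
the lower CE — so identical measurement tables always produce identical
panels.

Blank-matrix curation drops a transition when its blank intensity reaches
5 % of its best standard intensity. The threshold operationalizes what is
otherwise a manual curation step and is configurable; 0 makes any nonzero
blank fatal. Panels take the top 8–10 curated survivors; fewer than 8
yields a degraded panel with a warning, zero survivors is a hard error.

## Carrier (MaxRec) peptides

Carriers must mimic the target (same length, Hamming distance ≤ 2,
|ΔGRAVY| ≤ 0.5 by default) while being invisible to the monitored
transitions. Blindness is evaluated on theoretical m/z only — the claim
rests on quadrupole selectivity, not retention time: for every monitored
precursor charge, the candidate precursor must clear every panel Q1 value
by ≥ 2 Th, or, where it clashes, every candidate b/y product must clear the
clashing panel Q3 values by ≥ 1 Th. The 2/1 Th defaults reflect
unit-resolution isolation windows and are configurable. Near-isobaric
substitutions (|Δresidue| < 0.5 Da, including L↔I and K↔Q) are excluded
up front because they can never achieve Q1 separation.

Survivors are ranked by |ΔGRAVY| ascending, then blindness margin
descending, then sequence order. The pipeline searches single substitutions
first and widens to two only when nothing survives — distance-1 candidates
are maximally similar physically, which is the point of the carrier. A
residue-class-preserving filter (hydrophobic→hydrophobic, etc.) stands in
for instrument "detectability", for which no public model exists; it is off
by default and documented as an approximation. The search is this package's
own; no claim is made that it reproduces any proprietary carrier sequences.
Every designed carrier is verified blind against the panels of *all*
targets in the run, not just its parent's.

## Quantification

Per replicate the detected ratio is Σ light areas / Σ heavy areas over the
signature transitions — summing before dividing damps weak-transition
noise (a per-transition-median alternative is available behind a flag).
Abundance = mean ratio × spike (amol); copies per cell =
amol × 10⁻¹⁸ × 6.02214076 × 10²³ / cell count, rounded half-up to one
decimal to match reporting convention. The benchmark fixtures use a
500 amol spike and 5 × 10⁷ cells; the spike value is inferred from the
internal self-consistency of the benchmark table (abundance/ratio is
constant at 500 ± 0.1 amol across all 11 assays) rather than stated by any
single entry, and is a required input for user data. A target is flagged
non-detectable when its light signal is zero or fails a 3:1
signal-to-blank rule (configurable); zero heavy signal is a hard error
because the standard itself was not detected. Fold gains with/without the
carrier cocktail are per-target ratio quotients; a zero baseline is
reported as infinite gain and excluded from the mean.

## Simulator

The simulator supplies the statistical structure the design and
quantification stages assume, nothing more:

* CE responses are Gaussian in CE (width 4–8 eV, true optimum within
  ±3 eV of theoretical) with unit-mean log-normal multiplicative noise;
  real fragmentation curves are asymmetric and can saturate.
* Peak intensities decay geometrically over a shuffled rank to create an
  intensity hierarchy; real intensity ratios depend on sequence.
* Blank interference is a fixed fraction of the standard's peak on chosen
  transitions; real matrix interference is retention-time dependent.
* Area tables apply one log-normal factor per replicate to the implied
  true ratio, so the replicate CV is the configured value; real variance
  has transition-level structure too.

Passing tests against this generator therefore demonstrates the
correctness of the selection/quantification logic under its stated
assumptions, not instrument-level performance. All simulators are
bit-reproducible under fixed seeds.

The packaged benchmark set carries short excerpts of canonical human KRAS,
TP53 and IDH2 around the assayed hotspots (sha256-prefixed checksums guard
the strings; every mutation validates its reference residue on load), 11
assay entries spanning 9 distinct missense mutations, and area tables whose
three replicate ratios are placed at mean − sd / mean / mean + sd so the
tabulated mean and sample sd are reproduced exactly. The full 11-target
pipeline (design, carrier cocktail, quantification) runs in well under a
minute on one CPU; recovery studies use 100 CE trials and 200 quantification
trials, sizes at which their pass criteria are statistically stable.

## Known limitations

No retention-time prediction or scheduling, no dwell-time allocation, no
isotope-envelope or chromatogram simulation, no PTMs beyond the heavy
label, no vendor method export, no HLA-binding prediction (deliberately:
enumeration is exhaustive instead). The mean with/without-carrier fold
gain computed by per-assay division of the benchmark ratios is ≈ 29.5
(range ≈ 1.8–67.9); rounded summaries of such gains elsewhere should be
treated as approximate, and this package reports only what it computes.
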