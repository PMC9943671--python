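# Methods

This note documents the models implemented in `nanoladder`, their
assumptions, the defaults that matter, and the choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Probe design

A circular DNAzyme probe is designed against one purine–pyrimidine (R–Y)
dinucleotide junction of the target RNA. The 10–23-class DNAzyme cleaves
between a purine and a pyrimidine, so the site scan reports every adjacent
R–Y pair; `flank_ok` requires at least one arm length of sequence on each
side of the junction (the purine counts toward the upstream flank).
Coordinates are 0-based with half-open windows; circle positions are taken
modulo the circle length.

- **Arms.** 20 nt each by default, exact reverse complements of the target
  windows flanking the junction. `arm_5p` binds the downstream (3') flank and
  `arm_3p` the upstream flank because probe and target anneal antiparallel.
  The one-base 3' overhang left by cleavage is not modeled at sequence level;
  its effect is folded into the simulator's detection-efficiency parameter.
- **Catalytic core.** Defaults to the canonical 10–23 core
  `GGCTAGCTACAACGA`; any core sequence may be supplied — the designer treats
  it as an opaque string positioned between the arms.
- **Site ranking.** When several junctions are usable the preference order is
  AU > GU > AC > GC, the standard 10–23 activity ranking; configurable.
- **Reference region and barcode anchor.** 20 nt each, drawn by seeded
  rejection sampling under orthogonality constraints: GC fraction 40–60%, no
  homopolymer longer than 4, and no 10-mer shared (either strand) with the
  target or with previously accepted pool members.
- **Controls.** `SNV` substitutes the single central base of the recognition
  region; `MM12` substitutes exactly 12 bases spread evenly across it;
  `random` replaces it with a GC-matched (±5%) sequence sharing no 10-mer
  with the original; `core_deleted` swaps the catalytic core for an inert
  spacer of equal length. All are deterministic given a seed.
- **Specificity screen.** For each background sequence the report gives the
  longest contiguous complementarity per arm (dynamic-programming longest
  common substring of the arm's target-sense window) and a cleavage-competence
  prediction: the full recognition window is slid over the background at its
  best ungapped placement, and any mismatch within ±8 nt of the junction
  (configurable) abolishes predicted cleavage — central mismatches are what
  kill DNAzyme activity, which is the mechanism behind SNV discrimination.
- **Padlock/linker.** The circle is linearized in the middle of the catalytic
  core so the ligation junction sits inside the core; the 20-nt linker
  reverse-complements the padlock's 3' then 5' termini (10 + 10 nt).

## Virtual-code codec

A virtual code is the vector of DFP repeat levels across detection channels.
Levels run 1..R; zero levels are excluded so that every decodable spot is
visible in every detection channel (this is also what makes the two-channel,
three-level design yield exactly 3² = 9 codes). Capacity over n sequential
imaging rounds is n·R^C. Theoretical ratios are
`level_c · brightness_c / (norm_level · brightness_ref)` with the
normalization level defaulting to the design's maximum — under which the
single-channel ten-level ladder spans 0.1…1.0. Codes are enumerated
lexicographically and assigned to transcripts in input order, so codebooks
are deterministic; serialization is versioned JSON and round-trips exactly.

## Synthetic data

The generator emulates the statistical structure the decoding analysis
relies on, not the optics of any particular microscope.

- **Copy numbers.** Per cell and gene, true copies ~ NB(mean, dispersion)
  with dispersion (NB size) 5 by default — overdispersed cell-to-cell
  variation. The default nine-gene panel uses means between 4 (ER) and 40
  (GAPDH) copies per cell, with PFN1 at 24 and ER at 4 taken from printed
  single-cell ranges (18–30 and 1–9); the others are plausible values for a
  cultured epithelial line, chosen once for the synthetic regime.
- **Detection.** Amplicons = Binomial(copies, p_det) with p_det = 0.30,
  matching reported in situ detection efficiencies near 30%.
- **Amplicon repeats.** K ~ round(lognormal(ln 60, 0.5)), minimum 1. No
  distributional form is published for RCA repeat counts; a right-skewed
  lognormal captures the nonuniform amplification the ratio normalization
  exists to cancel. Configurable.
- **Probe binding.** bound_DFP,c ~ Binomial(K·level_c, h_DFP) and
  bound_RFP ~ Binomial(K, h_RFP) with h = 0.8 by default (hybridization in
  crowded cytoplasm is incomplete; no published value — engineering choice).
  Intensities are brightness × bound counts with optional Poisson shot
  noise. At h = 1 and shot noise off the De/Re ratio equals the repeat level
  exactly for every K, which the tests assert verbatim.
- **Nonspecific background.** Per cell ~ Poisson(λ), λ = 16 in
  primer-assisted mode and 0.2 in RNA-primed mode (parameter echoes of the
  reported contrast, not re-derivations). Each background spot carries a
  uniform random level in one random detection channel and K from the same
  law — deliberately decodable-looking so it stresses the rejection logic
  rather than being trivially dim.
- **Geometry and rendering.** Cells are disks (radius 45 px ≈ 14 µm at
  0.16 µm/px) on a grid; amplicon positions are dart-thrown with a 6 px
  minimum separation (waived per point after 200 failed attempts, so dense
  cells remain valid). Stacks have 5 z-slices at 500 nm spacing; each spot
  renders as a 2D Gaussian (σ = 1.3 px) in its nearest slice with integral
  equal to its channel intensity, over constant background 100 with Gaussian
  read noise σ = 2 and 16-bit saturation clipping. A DAPI channel carries the
  nucleus disks. Channel crosstalk is zero by default.
- **qPCR.** Ct = intercept − slope·log10(mean copies) + N(0, σ) with slope
  1/log10 2 (perfect doubling), so 2^–ΔΔCt recovers fold changes exactly at
  zero noise.

What the generator does *not* emulate: optical crowding and amplicon
overlap, autofluorescence, non-Gaussian PSFs, spatial expression patterns,
and hybridization efficiency that depends on barcode size. Passing tests
therefore demonstrate the correctness and statistical behavior of the
algorithms under these assumptions, not performance on real micrographs.

## Spot calling

Detection operates on per-channel maximum intensity projections (matching
standard acquisition practice; full-3D detection is an extension point).
The detector bandpasses with a scale-normalized negative Laplacian of
Gaussian (blob scale 2 px), thresholds at median + 5 robust-MAD of the
bandpassed plane, applies non-maximum suppression at 3 px (two closer spots
merge into the brighter one), and refines centroids by center of mass in a
5×5 window. On a noiseless plane the MAD is zero; the threshold then falls
back to 1% of the peak bandpass response, and a constant plane yields no
spots. Photometry is aperture sum minus annulus-median background times
aperture area, clamped at zero, with a border-clipping flag. Matching is
mutual nearest neighbor within 2 px, anchored on reference-channel spots;
distance ties break toward the lower spot index, and unmatched detection
channels contribute intensity zero. Cell assignment reads the label mask at
the rounded centroid. All steps are deterministic.

## Decoding

Ratios r_c = I_De,c / I_Re are defined only for positive reference
intensity; spots failing that are rejected outright. Calibration estimates a
per-channel scale s_c mapping observed ratios onto integer levels: a coarse
geometric grid over s ∈ [1/3, 3] minimizes the median level-relative
residual of r/s (ties resolved toward the identity scale), followed by two
median-refinement passes `s = median(r / nearest level)`. The grid stage is
needed because naive nearest-integer rounding cannot recover a global
doubling of all ratios — it latches onto wrong levels; the grid restores a
basin of attraction and the median refinement then converges. Calibration is
per field, not per cell: single cells carry far too few spots (~1–30).

Classification assigns the code minimizing Σ_c |r_c/s_c − ℓ_c| / ℓ_c. The
distance is level-relative because the binomial spread of bound probes grows
with level, so absolute distance would over-penalize high levels. A spot is
rejected when the best distance exceeds the margin 0.35 (fixed a priori, in
level-relative units), when the two best codes tie (within 1e-9), or when
any calibrated ratio falls below 0.5 — below the lowest level, where
degenerate and single-channel nonspecific spots land. Under the level-
relative metric the equidistant point between adjacent levels is not their
arithmetic midpoint (for levels 1 and 2 it is r = 4/3), and the tie rule is
defined on the metric itself. Decoded plus rejected counts always equal the
input spot count, and decoding is invariant to any global intensity rescaling
(ratios and calibration both cancel it).

## Quantification

Expression matrices aggregate assigned spots per gene and cell; rejects are
excluded but reported. Detection efficiency is mean(observed)/reference with
a Wilson interval treating pooled observed counts as binomial out of
n_cells × reference-mean trials. Fold change follows 2^–ΔΔCt with replicate
Ct values averaged per sample/gene first. Cell-type discrimination uses
leave-one-out nearest-centroid on log1p counts — chosen for determinism and
zero hyperparameters given the small per-cell counts (0–30); log1p because
Euclidean distance on raw small counts is dominated by the high-mean genes.
Absolute copy-number conversion from Ct values is supported only through
user-supplied standard-curve slope/intercept, since no universal curve
exists.

## Problem sizes and tolerances

The shipped test and acceptance workloads use 4–500 cells per simulation,
64–220 px fields, and 5 z-slices — sizes chosen so every statistical check
has comfortable power (e.g. ~21k spots behind the nine-plex accuracy figure)
while the full suite runs in well under a minute of compute per module.
Statistical assertions use explicit sampling tolerances (3 standard errors
for means, nominal-coverage allowances for interval checks); exact
assertions (ratio = level at zero noise, conservation laws, serialization
round-trips) are made with equality, not approximation.
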