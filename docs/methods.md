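# Methods

## Scope and model

`ismn` scores the in-vitro micronucleus (MN) assay from single-cell
imaging-flow-cytometry crops, multiplexed with three DNA-damage
biomarkers: ɣH2AX (Ser139, BV421 conjugate; double-strand-break
marker), pH3 (Ser28, AF488; mitosis marker) and p53 (PE; general
damage-response marker), plus a far-red DNA stain for nuclei and MN.
Per-dose endpoint metrics are reduced to fold changes versus the
vehicle control and combined into a mode-of-action (MoA) call:
chromosome breakage (clastogenic: ɣH2AX up, pH3 not up) versus
whole-chromosome loss (aneugenic: pH3 up, ɣH2AX not up), with MN or
p53 positivity required as the damage evidence.

Because real instrument data are not needed for development or
validation, the package ships a first-class synthetic-image generator
with complete ground truth; every pipeline stage is tested against
known labels.

## Segmentation (mask stack)

Per cell, on the DNA channel:

1. **Lower-intensity threshold** — drop the lowest 10% of pixel
   intensities (inclusive tie rule: a constant image keeps all pixels).
2. **Spot mask** — bright-blob detection implemented as a white
   top-hat (separable square window, side = max spot diameter + 1 px),
   local maxima above a robust noise floor (6 × MAD of the residual),
   flood-grown half-maximum supports, a peak-to-local-background ratio
   ≥ 1.5 ("low"), and an equivalent-diameter bound of 1–6 px.  Two
   guards reject look-alikes: supports are grown outside the segmented
   nucleus (padded 2 px) so nuclear-rim blur residuals cannot bridge
   into spots, and a peak whose support boundary is at least as bright
   as the peak itself is discarded (a flat plateau, not a spot).
3. **Range filter** — keep components with area 1.25–25 µm² (pixel
   count × pixel-size², 0.5 µm/px default) and covariance-ellipse
   aspect ratio 0.4–1; bounds inclusive.
4. **Nucleus** — Otsu seed on the lightly smoothed image (a disk(2)
   binary opening first cuts thin blur bridges between nucleus and
   nearby MN), refined by a morphological Chan–Vese active contour
   (4 iterations; smoothing = 4 − contour_detail, default detail 3)
   restricted to a 2-px band around the seed so the contour tightens
   the boundary without annexing nearby bright objects; dilated 1 px;
   size-filtered to components larger than the 25 µm² MN cap.
5. **Boolean subtraction and combination** — three spot→range→subtract
   iterations (iteration 2 relaxes roundness to 0.3–1, iteration 3
   widens the diameter bound to 1–8 px), OR-combined, AND-ed with the
   cytoplasm (brightfield cell extent minus nucleus), border-touching
   components dropped.  Spots are counted as 8-connected components.

The "1–6 pixels" bound is treated as a **diameter** and "1.25–25 µm"
as an **area in µm²**; both interpretations are configurable.  The
three iterations' exact settings are package defaults, not a claim
about any vendor's internals.

## Features

Brightfield: cell mask (largest below-Otsu dark component,
hole-filled), aspect ratio (minor/major axis of the coordinate
covariance ellipse), area (µm²), gradient RMS (RMS of the
first-difference gradient magnitude — the focus measure), and
cytoplasmic contrast (coefficient of variation of intensity).
Contrast is measured on the cytoplasm *inside* a 2-px-eroded cell
boundary: without this, the focus-dependent edge gradient dominates
the measure and systematically fails large-nucleus (G2/M) cells at the
health gate — in testing roughly half the mitotic population was
otherwise lost.

Similarity of morphology is the Fisher z-transform (atanh) of the
Pearson correlation between a biomarker channel and the DNA channel
over the whole-cell support (both compartments are needed to
discriminate nuclear from cytoplasmic signal); r is clipped to
±(1−10⁻⁶).  Scores > 1 read as nuclear, < 0 as cytoplasmic, 0–1
intermediate.  Integrated intensities are plain sums over the nucleus
and whole-cell masks; the whole-cell support includes the nucleus so
nuclear ≤ whole holds by construction.

## Gating

* **QC**: aspect ratio > 0.6, brightfield area 70–450 µm² (strict
  bounds), gradient RMS > 50.
* **Health**: nuclear area above the 10th and cytoplasmic contrast
  below the 90th percentile of the stained vehicle population
  (inclusive, so a degenerate all-identical population is all
  healthy).  Percentiles are used because no absolute thresholds are
  published; 10/90 rather than quartiles because the gate exists to
  drop the distressed tail, not to halve a healthy population.
* **DNA content**: integrated DNA intensity > 1×10⁵ (the synthetic G1
  peak sits at ~2×10⁵ by construction).
* **Cell cycle**: Gaussian KDE (Silverman's rule, log scale, where
  both peaks share a relative width) finds the dominant G1 mode; the
  G1 gate is the mode ± 2× its half-maximum half-width; G2/M is the G1
  gate scaled by 1.9 (configurable within the 1.8–2 convention) with
  the lower bound extended to the 1st percentile of pH3-positive
  cells; S is the open interval between.  Gates are refit per sample
  when ≥ 500 cells are available (the DNA histogram drifts between
  acquisitions), else the pooled fit is used.
* **Biomarkers** (per channel): unstained-peak (UP) gate = central 99%
  of the unstained sample (coordinate-averaged over multiple unstained
  samples); tenfold gate = UP × 10 (the p53 variant lowers the lower
  bound to 0.9 × UP-max, since constitutive p53 sits just above
  background); stained-peak (SP) gate = half-maximum interval around
  the log-KDE mode of stained cells above the tenfold lower bound
  (falling back to the tenfold gate below 20 cells); combined-average
  gate = element-wise mean of tenfold and SP.  The ɣH2AX +/++ boundary
  is the geometric mean of the vehicle-stained and treated-stained
  secondary-peak modes, the treated mode searched above the vehicle SP
  interval; all stained samples inform it so it can be placed even
  when treatment suppresses the induced population.
* **Populations**: pH3⁺ = nuclear AF488 above the combined-average
  lower bound (and DNA-positive); ɣH2AX ++ = nuclear BV421 above the
  +/++ boundary; overall p53 = whole-cell PE above the combined-average
  lower bound.  True-nuclear populations additionally require
  similarity > 0 — the intermediate 0–1 band is deliberately included
  because biomarker phosphorylation is dynamic.  The MN-eligible
  population is healthy, pH3-negative, DNA-positive and
  single-nucleus.

## Analysis

Replicate-level endpoint fractions (MN frequency on the mononucleated
population; pH3 and p53 on healthy DNA-positive cells; ɣH2AX on the
pH3-negative subset, separating mitosis-associated from
damage-associated signal) feed a distribution-checked cascade:
Bartlett and Shapiro–Wilk (on within-group residuals) at p > 0.05 gate
a one-way ANOVA plus Dunnett comparisons versus vehicle (fixed
quadrature seed — the multivariate-t integration is randomized and
would otherwise break run determinism); otherwise Dunn's rank z-test
versus control (tie-corrected, unadjusted p, implemented here because
no installed package provides it) on the raw responses.

Per-dose metrics are means of replicate fractions; fold changes are
treated/vehicle, square-rooted for display and thresholding.
Cut-offs (raw scale): pH3 1.3 up / 0.7 down, ɣH2AX and p53 1.5 up,
MN 2.0 up; the sqrt-scale values are computed by square-rooting and
rounding to one decimal (1.1 / 0.8 / 1.2 / 1.4), with an exact-sqrt
option.  A biomarker endpoint is positive when the mean response
exceeds its cut-off **or** is statistically significant; MN is
significance-first with the twofold fallback.  Endpoint calls for the
MoA are made at the highest dose whose relative cell growth (RCG =
100 × treated/vehicle cell concentration) still reaches 30%, the
assay's cytotoxicity limit.

The overall call requires damage evidence (MN or p53 positive) before
a direction is assigned: clastogenic (ɣH2AX up, pH3 not up),
aneugenic (pH3 up, ɣH2AX not up), equivocal (damage evidence with an
uninformative signature), negative (no damage evidence).  An isolated
biomarker fluctuation without any damage endpoint therefore reads
negative, not equivocal — MoA inference is only meaningful when both a
damage endpoint and a biomarker respond.  p53 contributes to
positivity but not to direction.

## Mask benchmarking

%Accuracy = 100 × truly-MN-containing flagged cells / flagged cells.
The published %Miss Rate formula (100 × mask-detected true MN /
manually identified true MN) computes a *detection* proportion; both
the as-printed value and its complement are reported under explicit
labels rather than silently redefining either.  A mask component
matches a true MN when its centroid lies within 2 px of the true
centre (matching by eye needs a rule).  Benchmarks run on the "DNA
Focus" subpopulation: DNA-channel gradient RMS strictly above the
population median.

## Synthetic data

The generator emulates ImageStream-like 64×64 crops at 0.5 µm/px.
Choices, fixed once (no quantitative image-formation details are
published, so amplitudes are free parameters of the package):

* Geometry: cell radius 15 px (7.5 µm — TK6-like), G1 nucleus radius
  6 px; nuclear area scales with cycle stage (G2 = 1.9 × G1 at a fixed
  per-pixel DNA amplitude of 1770, so G1 integrates to ~2×10⁵); MN are
  discs of 1.25–3 µm placed ≥ 3 px outside the nucleus edge and ≥ 4 px
  apart, with the cell radius grown adaptively when large MN need
  room.
* Population (vehicle baseline): G1/S/G2/M = 0.55/0.25/0.14/0.06
  (pH3⁺ = M); ɣH2AX induced 8% over a 40% constitutive tier; p53
  positive 15%; MN-bearing cells 3% (1–3 MN: 85/13/2%); 5% of positive
  cells carry cytoplasmic (off-target) signal that the similarity
  refinement should remove.
* Intensities: per-channel lognormal autofluorescence (σ = 0.25) over
  the cell disc; stained tiers (e.g. ɣH2AX background 3.5×10⁴, induced
  3×10⁵ integrated counts) placed so that UP × 10 lands at the
  background-stained level, as in real panels.  Brightfield is a dark
  disc (depth 700 on a 1000 background) whose edge gradient keeps
  in-focus cells above the gradient-RMS 50 gate.
* Optics/camera: Gaussian blur σ = 0.8 px, additive Gaussian noise
  σ = 10 (clipped at zero), per cell-channel.
* Dose effects: multiplicative shifts on the baseline rates,
  interpolated linearly in dose to the stated top-dose values;
  clastogen = ɣH2AX ×2.5, pH3 ×0.5, p53 ×2, MN ×2.5, RCG 50% at top;
  aneugen mirrors ɣH2AX/pH3.  `cells_per_dose` counts cells per dose
  *per replicate*; two unstained samples (vehicle and top dose)
  accompany every study for gate calibration.
* Seeding: one master seed; per-sample and per-cell seeds derived
  deterministically, so whole experiments are bit-reproducible.

What the generator does **not** emulate: optical point-spread
structure, doublets/debris, brightfield texture, spectral spillover
(inputs are assumed compensated), staining-batch drift, or the real
phenotypic diversity of MN (hypo-intense, apoptotic-body-like,
nucleus-touching).  Passing tests therefore demonstrate the
*machinery* — masks, gates, statistics, calls — under controlled
conditions, not field performance on instrument data; the published
real-image accuracy (~57%) and miss rates are not reproducible from
synthetic discs and are not targeted.

## Problem sizes and numerical choices

Desk-scale runs use 4 doses × 3 replicates × 200 cells (the
scored-cell minimums of ~13,000 healthy / ~10,000 mononucleated cells
per dose apply to instrument-scale studies and default to warnings
only, thresholds configurable).  The end-to-end validation runs one
clastogen, one aneugen and twenty null studies.  Statistics
calibration uses 1000 simulated null experiments (3 replicates × 5
doses).  Degenerate inputs are handled explicitly: constant images at
the percentile threshold (keep all), zero-variance channels in the
similarity score (NaN, flagged), all-identical populations at
percentile health gates (all healthy) and in the test cascade (p = 1,
no positives), empty masks (errors for undefined statistics, zeros
for counts), segmentation failures (flagged records, not exceptions).

## Known limitations

* The spot detector is tuned for round, well-separated MN; merged MN
  are counted as one (no watershed splitting by design).
* Binucleate (cytokinesis-block) scoring is out of scope.
* Dunn's p-values are unadjusted; Dunnett's control the family-wise
  rate — the two branches therefore differ in multiplicity behaviour,
  as in the original cascade.
* Benchmark-dose modelling is not included; per-dose tables are
  exportable for external BMD tools.
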