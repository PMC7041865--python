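# Methods

`histoquant` quantifies fluorescence images of tumor tissue sections: how
many cells stain positive for viability markers (proliferation, apoptosis,
autophagy), and how much of a fluorophore or fluorophore-labeled drug a
tissue has taken up. Everything downstream of image acquisition is covered:
nucleus segmentation, per-cell positivity calling against a secondary-only
control, percent-positive reporting with group statistics, whole-tissue
intensity quantification split by viable/necrotic annotation, and
quality-control arithmetic for the labeled reagents themselves. A
ground-truthed synthetic scene generator stands in for slide scans, so every
stage is testable end to end.

## Nucleus segmentation

The chain is classical mathematical morphology on the DAPI channel:

1. **CLAHE.** Contrast-limited adaptive histogram equalization onto [0, 1].
   Implemented in-package with explicit tile semantics: per-tile histograms
   (256 bins over the global range), clipping at `clahe_clip` × tile pixel
   count with uniform redistribution of the excess (single pass), cumulative
   mappings, and bilinear blending between tile centers. With one tile and
   `clahe_clip = 1` the operation reduces exactly to plain histogram
   equalization, which the tests verify against a rank-based oracle.
   Defaults: 64-px tiles, clip 0.01.
2. **White top-hat.** Image minus its opening with a disk of radius
   `ceil(nucleus_radius_um / pixel_size_um)`. The structuring element must
   *not* fit inside any nucleus, otherwise the opening reconstructs that
   nucleus and deletes it from the top-hat response; `nucleus_radius_um`
   therefore defaults to 8 µm, the upper end of the 5 ± 0.75 µm radius
   distribution the generator assumes, rather than the mean radius.
3. **Foreground.** Otsu threshold on the top-hat output (overridable with a
   fixed value), followed by binary hole filling — large nuclei close to the
   structuring-element size leave ring-like top-hat responses whose
   interiors must be recovered.
4. **Seeds.** Euclidean distance transform of the foreground, h-maxima
   suppression at depth `h_maxima_depth` (default 0.3 px), one candidate per
   plateau (deepest pixel, row-major on ties), then single-linkage merging
   of candidates closer than `min_seed_separation_px` (default 4 px,
   deepest member kept). The shallow depth splits touching nuclei
   aggressively; the separation merge absorbs the discretization plateaus
   that elongated nuclei produce along their medial ridge.
5. **Watershed.** Seeded watershed flooding the negated distance transform,
   restricted to the foreground; seeds are labeled 1..K in row-major order,
   ties resolve deterministically, and foreground components unreachable
   from any seed are attached to the nearest labeled pixel so the labels
   exactly tile the mask.
6. **Removal.** Objects outside [20, 400] µm², below solidity 0.8, or more
   than half-covered by the artifact mask are dropped; survivors are
   compacted to 1..K. Removed clusters are excluded from analysis, never
   silently split.
7. **Cell partition.** Every tissue pixel is assigned to the nucleus with
   the nearest pixel (Euclidean, in µm); the distance map holds that
   distance, zero inside nuclei. This is the Voronoi partition used for
   cytosolic marker scoring and distance-based summaries.

Coordinates are 0-based (row, col); areas are µm² via `pixel_size_um`².
All stages are deterministic: identical input and configuration give
bit-identical label maps.

## Positivity calling and viability reports

Stained images are normalized to a secondary-only control by subtracting the
control channel mean (clipped at zero); the control captures additive
autofluorescence and nonspecific secondary binding. Division by the control
is deliberately not the default because the dominant artifact is additive.
The binarization threshold for a marker is control mean + `k_sigma` × sd
(default k = 3) on the normalized scale.

Events are counted by nuclear overlap for all markers. Nuclear markers
(Ki67): positive when supra-threshold signal covers ≥ 50% of the nucleus.
Cytosolic markers (cleaved caspase-3, Beclin 1): positive when
supra-threshold signal covers ≥ 10% of a 2-px-dilated nucleus rim restricted
to the cell's own Voronoi region — cytosolic staining hugs the nucleus, and
requiring rim overlap prevents a neighbour's signal from being credited to
the wrong cell. Both fractions are configurable.

`percent_positive` pools counts over sections (100 · Σ positives / Σ cells);
the SEM is computed across section-level percentages, the section being the
biological replicate. QC flags conditions below 5000 total nuclei or 10
ROIs (inclusive bounds); failing conditions are reported, never dropped.
Group comparisons use one-way fixed-effects ANOVA with no multiplicity
correction, reported with group means and SEMs. No dose-response model is
fitted; per-cell intensity tables are exported for such analyses.

## Whole-tissue uptake

The analysis ROI is the tissue foreground (triangle threshold of a σ = 2 px
Gaussian-smoothed channel with hole filling, or a user-provided mask for
manually drawn ROIs) eroded by round(border_um / pixel_size_um) pixels —
10 µm by default — minus any fold/cutting artifact mask. Erosion is
implemented as a Euclidean distance threshold to the mask complement
(image boundary included), so a rectangular tissue of H×W keeps exactly
(H−2b)(W−2b) pixels for a b-pixel border. The uptake statistic is total
intensity over the ROI divided by its pixel count, computed on raw counts.
Control (uninjected/unstained) tissue is summarized identically and reported
as a parallel baseline, never subtracted. Viable and necrotic regions
(externally delineated masks) are summarized independently; per-section
region means feed the same ANOVA for the significance statement. Dose
titrations report mean ± SEM per dose with a Spearman-sign monotonicity
flag; single-replicate doses are flagged and carry no SEM.

## Reagent QC

Monoisotopic masses use a bundled IUPAC/CODATA table (≥ 6 decimals);
protonated m/z is (M + z·1.007276)/z — the proton mass, not the ¹H atom
mass, which matters in the fourth decimal — rounded to 4 decimals as HRMS
reports print. Degree of labeling is the Beer–Lambert quotient
(A_max/ε_dye) / ((A₂₈₀ − CF·A_max)/ε_protein); ε and CF are user inputs with
no dye-specific defaults. The acceptance band for antibody conjugates is
1.1–3.3 inclusive.

## Synthetic scenes

The generator emulates scanned cryosections: rotated elliptical nuclei
(radius ~ Normal(5, 0.75) µm truncated at 2 px, aspect 1.15–1.6) on additive
Gaussian autofluorescence (mean 60, sd 8), one channel per marker. Default
field: 1024² px at 0.5 µm/px with 1200 nuclei; the per-section variant for
multi-section studies is 512² px with ~250 nuclei, so 20 sections hold
~5000 nuclei, the QC floor. Positivity is Bernoulli per nucleus so
section-to-section SEM behaves like biological sampling. Nuclear markers add
signal inside positive nuclei; cytosolic markers in a 3-px-dilated annulus
clipped at Voronoi boundaries; DAPI stains all nuclei. Overlap pixels go to
the nucleus whose center is nearest in normalized ellipse coordinates.

A `touching_fraction` of nuclei (default 30%) is placed in contact with a
neighbour: anchored to the separated nuclei (without replacement), center
distance uniform between the overlap-cap separation and external contact,
and never closer than the cap separation to any other nucleus.
`touching_max_overlap` bounds pairwise area overlap (default 0.4); recovery
benchmarks in the tests use 0.2, since beyond ~20–40% overlap two flat-
rendered nuclei merge into a geometry that no binary-mask operator can
split — rendered nuclei are flat-topped, so unlike real chromatin-textured
DAPI there is no intensity valley at the contact. That is the main respect
in which passing tests understate difficulty on real data (texture helps) and
overstate it (flatness removes a cue real pipelines use).

Uptake scenes are single-channel, tissue filling the frame, with one
contiguous elliptical necrotic region at the requested area fraction and
Gaussian noise (sd defaults to the background sd). Fold artifacts are
bright bands doubling the local intensity, recorded in the ground truth.

Scenes are bit-identical for a fixed `rng_seed`. On disk, channels are
16-bit TIFF with a per-channel scale factor in the YAML sidecar: label
maps, masks and parameters round-trip exactly; float channels round-trip to
within one quantization step.

## Numerical choices and limitations

- Watershed tie-breaks and seed ordering are fixed (row-major), making label
  maps reproducible to the bit.
- Nearest-nucleus ties in the cell partition resolve deterministically via
  the distance-transform index propagation; tests treat either label as
  correct at exact ties.
- Otsu on a constant image returns an empty foreground rather than erroring.
- An empty ROI (border exceeding the tissue) is returned flagged with a
  warning, not silently.
- Identical constant groups give ANOVA F = 0, p = 1 (zero between-group
  variance) instead of NaN.
- Problem sizes in tests and the acceptance script — 5 scenes of ~1000
  nuclei for segmentation recovery, 20 sections × 5 fractions for positivity
  recovery, 200 replicate experiments for the uptake null — were chosen so
  each Monte-Carlo bound has comfortable resolution while the whole suite
  runs in minutes on one core.
- No machine-learned segmentation, no 3-D stacks, no stitching, no spectral
  unmixing, no cross-fluorophore intensity comparison (each channel has its
  own acquisition settings), and no automated necrosis detection — region
  masks are inputs by design.
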