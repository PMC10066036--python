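# Methods

This note documents the models and procedures implemented in `phagequant`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Cell model and geometry

Rod-shaped mycobacterial cells are modelled as 2-D spherocylinders
(capsules): a midline segment of half-width *r* closed by two semicircular
pole caps, with the boundary parameterised by arclength
(`phagequant.geometry.Capsule`). Pole-to-pole length is midline length plus
2*r*; circumference is 2·midline + 2π*r*. *Pole cap arcs* are the two
semicircles (every point there lies one half-width from a midline
endpoint); the *septum arc* is the boundary within 1 px of the mid-cell
plane when a cell carries a septum. Coordinates are row-major images with
origin top-left and pixel centres at integer coordinates; all polylines are
continuous (x = col, y = row). This single convention is applied everywhere
to avoid half-pixel drift between the simulator, segmentation and profile
sampling.

## Synthetic scenes

`phagequant.synthetic` generates the study conditions the quantification is
built for. Defaults (all in `SceneConfig`):

| parameter | default | meaning |
|---|---|---|
| `pixel_size` | 0.065 um/px | 100x objective on an sCMOS camera |
| `cell_length_range` | 2.5–5.0 um | *M. smegmatis* rod lengths |
| `cell_width` | 0.5 um | rod diameter |
| `polar_green_ratio` (ρ) | 2.0 | old-pole / new-pole label density; mycobacteria elongate faster from the old pole |
| `lateral_green_level` | 0.2 | lateral membrane label as a fraction of new-pole density |
| `phage_rate` (λ) | 3.0 | mean phage particles per cell (Poisson) |
| `polar_bias` (p) | 0.8 | probability an anchor is drawn in pole/septum arcs |
| `psf_sigma` | 1.5 px | isotropic Gaussian PSF, truncated at 4σ |
| `background_level` | 100 | camera offset per fluorescence channel |
| `poisson_scale`, `gaussian_read_sd` | 1.0, 2.0 | sCMOS noise model; each term independently switchable |
| `frame_interval` | 12 min | time-lapse cadence |
| `doubling_time` | 180 min | exponential length doubling |
| `old_pole_fraction` | 0.7 | share of added length at the old pole |
| `resistant_fraction` | 0.5 | infected cells that follow the outgrowth fate |
| `infected_dilution` | 1/1000 | seeder : uninfected mixing ratio |
| `n_operator_sites` × `protomers_per_site` | 7 × 2 | operator-array reporter; focus brightness scales with the product (14) |

Cells are placed by rejection sampling with a clearance test between
capsule midlines (error after a bounded attempt budget). For time lapses
the placement reserves each cell's final footprint, so growing cells never
collide; elongation is exponential with a 70/30 old/new-pole split. The
growth asymmetry and the per-phage photon yield (400 intensity units) have
no measured values to anchor them; they are config defaults with no claim
of realism. Membrane label is deposited along the boundary with
per-arclength density 1 on the new pole, ρ on the old pole and septum, and
`lateral_green_level` elsewhere, so the integrated old/new pole ratio is
exactly ρ before optics. Phage puncta are point depositions of
`phage_photons` at their anchor; with noise off, the red channel integral
equals the summed photon truth to <1% (PSF truncation). Reporter expression
rises sigmoidally from a drawn onset frame (level
amp/(1+exp(−(f−onset−1.5)/0.75)), zero before onset) and the cell is
removed at its lysis frame.

What the generator does **not** emulate: 3-D optics and defocus,
photobleaching, stage drift, uneven illumination, cell division (time
lapses elongate without dividing), phage detachment, autofluorescence
texture, and segmentation-error modes of real phase contrast (halos,
shade-off). Passing recovery tests on these scenes therefore demonstrates
the correctness of the measurement code under the stated imaging model, not
robustness to every artefact of real microscopes.

## Segmentation and single-cell geometry

Classical segmentation stands in for a learned segmenter: Gaussian smooth
(σ = 1), Otsu threshold on the inverted phase image, hole filling, area
filter, optional distance-transform watershed for touching cells. External
label masks (TIFF) can be ingested instead and flow through the identical
downstream contract. Per cell: the boundary is the longest marching-squares
contour at level 0.5, smoothed with a circular 9-point moving average
(raw marching-squares staircase overestimates a smooth perimeter by ~5%;
after smoothing a digital disk's circumference is within ~2.5% of 2πr).
The midline is the skeleton pruned to its longest path (two-pass BFS),
smoothed with a 7-point moving average to remove 8-connected zigzag, and
extended at each end to the boundary point farthest along the end tangent
(the pole points). Length = midline arclength + both cap extensions; width
= median of twice the Euclidean distance transform along the midline,
excluding midline points within half a width of either end. On synthetic
capsules, length is recovered within 2 px and per-cell IoU of re-rasterized
boundaries exceeds 0.95. Near-round regions (degenerate skeleton) fall back
to the boundary-diameter definition of length.

## Perpendicular-profile colocalization

Background per channel per frame is the mean and sample SD (ddof = 1) of
pixels farther than `dilation` px (default 5) from any labelled pixel, with
a minimum-pixel guard (default 500) against over-crowded fields. Lines are
anchored every `spacing` px of boundary arclength (default 2; at least one
line per cell so no cell silently drops out), with outward normals from the
central-difference boundary tangent over ±3 px of arclength, sign-fixed
against the centroid. Samples run from −`out_len` (3 px outside, where
surface-bound phage puncta sit) to +`in_len` (min(width/2, 6) px inside)
at 0.5 px steps, interpolated bilinearly; samples outside the image are
flagged invalid, and profiles are rounded at 1e-8 so bilinear floating-point
jitter cannot create spurious strict maxima in constant regions.

Peaks are strict interior local maxima; a plateau reports its leftmost
sample; endpoints are never peaks; NaN (invalid) samples split the profile
into independent runs. A line is phage proximal when its maximal red peak
height is strictly greater than background mean + k·SD (k = 1); the red
criterion uses the whole line because phage particles sit on the surface,
while the green (intramembrane) maximum is restricted to inside samples and
background-subtracted without clipping at zero, which keeps the null
distribution symmetric. Per condition the proximal and non-proximal groups
are summarised by median and quartiles. The spacing, lengths, step and the
raw-height (rather than prominence) threshold are this package's choices —
the underlying measurement protocol does not specify them — and all are
configurable.

A note on the null control: because both channels are sampled at the same
sub-pixel points, bilinear interpolation gives lines a shared,
grid-phase-dependent effective noise variance, which couples the extremes
of the two channels weakly even for independent noise. The effect is small
relative to the resampling band used for the null check (label-permutation
band for the proximal/non-proximal median difference, `coloc.null_band`),
but it is why the null is checked against a band rather than against zero
exactly.

## Adsorption statistic

The red channel is sampled along the full closed boundary at fixed
arclength steps; the circular profile is rotated to start at its global
minimum (deterministic, endpoint-safe) before linear peak detection. Peaks
below the background mean contribute zero (adsorption cannot be negative);
the floored, background-subtracted heights are summed and divided by the
circumference (pixels by default, micrometres when a pixel size is known —
the group comparison is unit-invariant). Two groups are compared with a
pooled two-tailed Student's t (df = nA + nB − 2); a Welch variant is
available; zero pooled variance with unequal means reports p = 0 with a
degenerate flag. Linearity of the statistic against true per-cell phage
count is calibrated on noiseless scenes with equal-length cells and uniform
surface anchoring (R² > 0.95 through the origin, counts 0–10); with
strongly polar dosing, overlapping puncta merge into single peaks whose
height under-represents their sum, a known saturation of peak-height
summation at high local density.

## Time-lapse tracking and fates

Tracking links labels in consecutive frames greedily by descending IoU
(admission threshold 0.5), each label used once per frame; at a division
the parent identity follows the daughter with the larger overlap and the
other daughter starts a new track. Traces are per-frame mask means minus
the per-frame background; onset is the first frame exceeding a threshold
for 2 consecutive frames (default 3× background noise SD). Fates for
tracks alive ≥ 5 frames: *expressed_lysed* when onset was detected and the
track ends before the movie does; *outgrowth* when no onset and final area
≥ 2× initial (requires an infected flag — ground truth in simulations,
external knowledge on real data — to be distinguishable from plain
uninfected growth); *uninfected* when no onset and not infected; otherwise
*censored*. A confusion matrix against ground truth is computed on every
simulation run.

## GC landscape

GC fraction is (#G + #C)/(#A + #C + #G + #T) with all IUPAC ambiguity codes
excluded from numerator and denominator (unbiased on draft sequences).
Sliding windows (default 500 bp, step 100 bp, 0-based half-open) are
computed by cumulative sums; low-GC regions merge runs of ≥ 3 consecutive
windows at least 8 percentage points below the genome mean. Window size,
step, drop threshold and minimum run are package defaults — no standard
criterion exists for "notably lower" — and are reported in the output
metadata. Region calls are validated by planted-segment recovery in
synthetic genomes (67% GC background, 2-kb 50%-GC inserts), not against any
real locus. The synthetic genome generator draws bases i.i.d. with
P(G or C) set per position; it reproduces composition only, not codon
structure, repeats or skew.

## Problem sizes and determinism

Every simulation is driven by `numpy.random.default_rng` on a single seed
carried in the config; identical configs give bit-identical scenes. The
acceptance script derives per-component seeds from its `--seed` via
`SeedSequence` spawning. Analysis problem sizes were chosen so recovery
statistics are well-resolved at desk scale: 100 cells (4 fields) for the
colocalization contrast and its null, 20 replicate pairs at 40 cells/group
for the adsorption comparison, 200 infected cells (8 movies of 20 frames)
for fate recovery, 500 cells for the Poisson dosing check, and 40-kb
genomes for region calling.

## Known limitations

- Peak-height summation saturates when puncta crowd within a PSF width;
  integrated-intensity measures would be needed for heavy aggregation.
- The proximal call with k = 1 admits many noise peaks at realistic noise
  levels; it follows the stated measurement definition, and group medians
  remain informative because false calls only dilute the contrast.
- Width from the distance transform assumes an approximately straight
  midline; strongly bent cells would need a curved-frame width.
- Tracking has no gap closing: a cell lost for one frame starts a new
  track.
- Fate classification separates resistant outgrowth from uninfected growth
  only when an infection flag is supplied.
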