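# Methods

`tunelquant` quantifies TUNEL-positive (TUNEL+) photoreceptor cells in
paired single-channel fluorescence micrographs of experimental retinal
detachment: a nuclear counterstain channel (e.g. DAPI) and a TUNEL channel,
16-bit grayscale TIFFs matched by filename stem. This note documents the
model behind each stage, the parameters that matter, the synthetic study
conditions used for validation, and the numerical choices and limitations a
user should know about.

## Pipeline model

Processing is four sequential stages per image pair.

**Stage 1 — outer nuclear layer (ONL) segmentation.** All counts are
restricted to the ONL, the dense band of photoreceptor nuclei. Two backends
satisfy one contract (a binary band mask):

* `model`: a learned probability map thresholded at 0.5. Training such a
  model (`train_onl_model`) is an optional feature requiring a
  deep-learning runtime; the loss it specifies — soft-Dice plus focal with
  positive-class weight 5.1 (the band occupies roughly a sixth of the frame,
  so positives are up-weighted against the ~6:1 background majority) and
  focusing exponent γ = 2 — is implemented and unit-tested as an ordinary
  NumPy function.
* `classical` (bundled default): the local mean of the Otsu-thresholded
  nuclear foreground over a 20 µm window is a nuclear-density map; Otsu
  thresholding that map, morphologically closing it (disk of half the
  window, with edge-replicating padding so the band is not eroded where it
  meets the image border), keeping the largest connected component, and
  filling holes yields the band. Closing precedes component selection so a
  local dip in nuclear density cannot split the band and discard half of
  it. On the synthetic panel this backend reaches a mean Dice above 0.9
  against the generative band.

**Stage 2 — background correction.** Rolling-ball background subtraction
(ball radius 6.5 µm, scaled to pixels by the calibration, nearest integer,
floor 1 px) removes uneven illumination and slowly varying
autofluorescence from both channels. The background estimate never exceeds
the image, so the corrected image is non-negative and bounded by the input;
a constant image maps to zero. Both channels are then rescaled by
percentile normalization (1st–99.8th percentile to [0, 1], no clipping) so
that downstream thresholds operate on a stable intensity scale.

**Stage 3 — instance segmentation.** Candidate cells are segmented in both
channels behind a single backend contract, `predict(image, prob_threshold)
-> LabelMap`:

* `stardist`: the pretrained star-convex polygon predictor for fluorescence
  nuclei, used when the optional dependency is importable; it is consumed,
  never re-implemented or re-trained.
* `fallback` (bundled default, no model weights): Otsu foreground of the
  input (identical mask semantics to the stage-4 classification mask, so
  instance areas are not blurred wide), Euclidean distance transform
  smoothed by 1 px, local maxima with a 3 µm minimum separation as seeds,
  and a seeded watershed. Each seed is scored by the image intensity at its
  peak pixel relative to the brightest peak; seeds below `prob_threshold`
  are discarded. The peak pixel sits on a cell's intensity plateau, so this
  score is nearly independent of cell size — a deliberate property, since
  the probability thresholds (0.5 and 0.65 in the bundled profiles) must
  not silently suppress small cells. Raising the threshold never increases
  the instance count.

**Stage 4 — dual-filter TUNEL+ classification.** The TUNEL channel's
preprocessed image is thresholded once by Otsu's method. Each candidate
from stage 3 is kept as TUNEL+ iff all three hold:

* area filter: `min_area ≤ area ≤ max_area` (µm², inclusive at both
  ends) — excludes sub-cellular debris below and fused clusters above;
* overlap filter: overlap fraction OF = |cell ∩ Otsu foreground| / |cell|
  is at least the overlap threshold (inclusive, OF ≥ 0.6 by default) —
  suppresses detections driven by background texture rather than genuine
  TUNEL signal;
* region restriction: the cell's rounded centroid lies inside the ONL
  mask. The centroid rule is deterministic and stable for boundary-
  straddling cells; it is applied identically to TUNEL+ candidates, to
  nuclei, and to both comparator counters.

Per sample the pipeline reports the TUNEL+ count, the nucleus count inside
the band, the band area in µm², and the nuclear density in cells/mm² of
band (density is defined as 0 when the band is empty). Units: all areas are
converted from pixels by 1/ppm² where ppm is the user-supplied
pixels-per-micrometer calibration; density divides the count by the band
area expressed in mm². The calibration is always a user input, never read
from TIFF metadata.

**Comparators.** Two reference counters isolate the contribution of the
dual filter: `otsu_only` counts 8-connected components of the stage-4 Otsu
mask under the same area filter and region rule (thresholding without
instance segmentation), and `stardist_only` counts stage-3 instances under
the same area filter and region rule but without the overlap gate. The
combined count is a subset of `stardist_only` by construction.

Note that with the bundled fallback backend the instance foreground *is*
the Otsu foreground, so OF is 1 for nearly every candidate and the overlap
gate is load-bearing only with an independent instance backend (such as the
star-convex model). The gate's semantics — inclusive threshold, exact
pixel-fraction computation — are unit-tested directly on constructed
label/mask pairs.

## Parameters

| parameter | default (`primary`) | `small-cell` profile | meaning |
|---|---|---|---|
| pixels_per_um | 1.5 | 1.5 | spatial calibration, px/µm |
| min_area_um2 | 10 | 4 | lower area bound, µm² |
| max_area_um2 | 60 | 15 | upper area bound, µm² |
| nuclei_prob_threshold | 0.01 | 0.01 | detection threshold, nuclear channel |
| tunel_prob_threshold | 0.5 | 0.65 | detection threshold, TUNEL channel |
| overlap_threshold | 0.6 | 0.65 | minimum OF for a TUNEL+ call |

The `small-cell` profile is the published recalibration for cohorts whose
TUNEL+ somata are markedly smaller; the profile-contrast test quantifies
exactly this trade-off (the standard window recovers under half of planted
5–14 µm² cells, the recalibrated profile over 90%).

## Synthetic study conditions

The generator (`tunelquant.synthetic`) renders calibrated image pairs with
exact ground truth: a sinuous nuclear band (40 µm thick, ~12% of the frame,
inside the 10–25% class-imbalance window typical of this tissue), ~180
densely packed band nuclei plus sparse outside nuclei, TUNEL+ somata of
known area planted inside the band (with co-located nuclear signal), debris
deliberately planted on both sides of the area filter, an additive
illumination ramp (default 15% of signal amplitude; the "heavy" condition
uses 100%), Poisson shot noise (gain 20), Gaussian read noise (sd 150
counts), and 16-bit quantization with clipping.

Planted objects are flat-top disks with an erf-shaped soft edge (edge σ =
0.4 px). The flat-top profile is what gives a planted cell a well-defined
area: the pixel area above any cut between roughly 20% and 80% of peak
height is close to the plateau area, so the generator can promise each
object's half-maximum area within ±10% of its target (it calibrates the
disk radius against its own rendering, at the object's subpixel position)
and that promise is meaningful to any reasonable downstream threshold. A
pure Gaussian peak has no such property — its area above a cut scales as
log(1/f) in the cut fraction f — which would make "planted area" an
artifact of the detector rather than a property of the object.

Objects are placed by sequential hard-disk sampling with a minimum
half-pixel edge gap. Nearly adjacent cells are intentional realism: nuclei
in the packed ONL touch, and close pairs are exactly what plain
threshold-and-count analysis fuses (one component, area above the cluster
bound, both cells lost) while watershed splitting preserves them. This —
not the illumination ramp itself, which rolling-ball correction removes
almost completely — is the dominant failure mode separating the
threshold-only comparator from the combined pipeline on dense samples.

What the generator does **not** emulate: optical point-spread blur beyond
the soft edge, chromatic misregistration between channels, retinal layers
other than one band, staining-intensity gradients within a cell, and
anisotropic or lobed cell shapes. Passing the synthetic panels therefore
demonstrates the correctness and internal consistency of the pipeline's
logic under controlled conditions, not its accuracy on any particular
laboratory's acquisitions — on real data the published workflow calibrates
the four post-processing thresholds on a handful of set-aside images.

## Numerical choices

* **Otsu implementation**: histogram with 256 equal-width bins spanning
  [min, max] of the image; class means are computed from exact per-bin
  intensity sums (not bin centers), so the maximizer agrees bin-exactly
  with a brute-force between-class-variance search on 8-bit images; ties
  break toward the lowest bin; the reported threshold is the midpoint
  between the brightest background and darkest foreground pixel; the mask
  uses strict `>`. A constant image is an error (callers treat it as zero
  foreground).
* **Percentile normalization** uses linear-interpolation percentiles and
  does not clip; a constant-range image maps to all zeros.
* **Area bounds and the OF threshold are inclusive**; boundary cases are
  pinned by tests (area 15 passes the small-cell profile, 15.01 fails;
  OF = 0.6 passes at threshold 0.6).
* **Empty-denominator conventions**: segmentation metrics are 1 when both
  masks are empty, else 0; density is 0 when band area is 0, and an empty
  band forces all counts to 0.
* **Bootstrap**: pairs are resampled with replacement; resamples with
  constant ranks are redrawn rather than scored as NaN, so all draws are
  effective; a single seeded NumPy generator makes every interval
  reproducible, and the seed is recorded in each report. Quartiles and
  percentile CIs use linear interpolation between order statistics.
* **Problem sizes**: the bundled validation studies use 30-sample cohorts
  with planted counts uniform in [5, 60] (and a 20-sample small-cell
  cohort), the cohort scale of the modeled experiments.

## Known limitations

* The classical band segmenter assumes one dominant dense band; retinas
  with severe disruption into multiple fragments keep only the largest.
* The fallback instance segmenter shares its foreground with the
  classification mask, so the overlap gate discriminates only with an
  independent (learned) instance backend.
* The centroid-in-band rule undercounts by design when the band mask is
  eroded at its edges; the density-based classical mask recovers ~90% of
  band pixels, which costs on the order of one edge cell per dense sample.
* Counts are per-section, two-dimensional; no stereological correction is
  applied.
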