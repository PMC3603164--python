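# Methods

## Scope and model

`entroseg` segments cell nuclei in 8-bit RGB histology images by global
per-channel thresholding and counts them as connected components. The
pipeline is: background removal → CLAHE → per-channel entropy thresholding
on a spatial-correlation histogram → mask combination → fill-holes + median
denoising → grayscale + Otsu → labeling. It assumes nuclei are darker than
tissue in red and green and brighter in blue (hematoxylin-type staining),
that empty slide regions are near-constant white, and that one global
threshold per channel is adequate — i.e. staining is reasonably uniform
across the field. Touching nuclei are counted as one component (no
watershed declumping), and no nucleus-type classification is attempted.

## Threshold selection

The similarity index g(x,y) counts the pixels of the N×N neighbourhood
within ε intensity levels of the center (inclusive comparison; the center
always matches itself, so 1 ≤ g ≤ N²). Borders are replicate-padded, so
every one of the P×Q pixels owns a neighbourhood and the two marginal
distributions share the denominator P×Q.

The operative normalized histogram ĥ(k,m) is the *product of the marginal*
intensity and similarity distributions. A true joint distribution of
(f, g) pairs is available via `EntropyConfig(joint_histogram=True)`; the
product form is the default because it is the computable definition the
method fixes, and the joint variant exists for experimentation. Both sum
to 1 by construction.

Region entropies use the 0·ln 0 := 0 convention for empty cells, and the
background region is the intensity set {t+1 .. 255} (the object set
{0 .. t} includes t, which is why red/green binarization is ≤ T). The scan
covers t ∈ {0..254}; values of t with an empty object or background
partition are excluded (their entropy is undefined) and reported as NaN in
the diagnostic curves. Ties in Φ(t) = H_O + H_B break to the smallest t,
making selection fully deterministic. The weight constant 32 in
w(m,N) = 5·exp(−(m−N²/2)²/32) is kept fixed for every N rather than scaled
with the neighbourhood size.

Defaults N = 5, ε = 5 suit mid-magnification fields; smaller values suit
lower magnification. Thresholds are *learned* on the preprocessed (masked +
CLAHE) components but *applied* to the original components; this asymmetry
is deliberate — CLAHE sharpens the distinction the entropy criterion sees,
while the original intensities define what a nucleus is. On strongly
bimodal channels the learned threshold transfers because any value in the
inter-mode gap separates the classes; `apply_on_enhanced=True` thresholds
the enhanced channels instead for images where the transfer is poor.

Implementation note: the t-scan is computed from per-intensity cumulants
(Σ ĥ ln ĥ·w and Σ ĥ·w per k), which is algebraically identical to the
direct double sum; the test suite verifies every intermediate quantity
against an independent nested-loop implementation at 1e-9.

## Preprocessing

Local range (max − min over a 3×3 replicate-padded window) is zero exactly
where a window is constant; the tissue mask is 1 where the product of the
three channels' range images is strictly positive. The strictly-positive
rule is parameter-free and the minimal reading of "convert the product to a
binary mask". A 5×5 median filter then removes isolated mask pixels and
pairs. Masked components enter CLAHE as-is (zeros included) — the simplest
behavior, at the cost of a spurious dark mode in heavily masked images;
`EntropyConfig(exclude_masked=True)` drops intensity-0 pixels from both
histogram marginals when that matters.

CLAHE uses a uniform (flat) target histogram, clip limit 0.01, and tile
side 5 px — i.e. one tile per non-overlapping 5×5 neighbourhood, matching
the 5×5 entropy neighbourhood. (A sliding-window reading of "number of 5×5
neighbourhoods" would mean one tile per pixel and degenerate CLAHE into a
local operation, so the non-overlapping reading is used.) `clahe_tile=None`
falls back to the conventional 8×8 tile grid for large images. Constant
channels pass through unchanged: there is no contrast to equalize and the
operation would otherwise be undefined.

## Postprocessing and counting

Fill-holes runs first (background regions not 4-connected to the border
become foreground; 4-connected background ⇔ effectively 8-connected
foreground, the standard complementary convention), and newly filled pixels
inherit their intensities from the *original* image — those values exist
and are the only meaningful choice, since the segmented image is zero
there. A 3×3 median filter per color component then removes single-pixel
salt noise. Counting converts the result to grayscale (luma weights
0.299/0.587/0.114), binarizes with Otsu's method (fixed 256-bin histogram,
smallest between-class-variance maximizer on ties; foreground is gray > T
because the background of a segmented image is exactly 0) and labels
8-connected components. No minimum-area filter is applied by default.

A property worth stating precisely: "denoising never increases the
component count" holds for the masks this stage actually receives —
blob-shaped objects with pinholes and isolated specks — and is verified
property-based over 100 randomized masks of that structure. It is *not* a
theorem for arbitrary binary noise: a 3×3 median filter severs single-pixel
bridges, so an iid-noise mask can gain components by splitting. Likewise
the support of a sharp-cornered rectangle is not median-stable (corners are
rounded); disks and blob-like supports are.

## Evaluation

Detected centroids are matched to ground-truth centroids greedily by
increasing distance, one-to-one, within `max_dist` (default: the mean
ground-truth nucleus radius, since nothing in a manual-count comparison
fixes a radius). Matches are TP, unmatched detections FP, unmatched truths
FN. TN follows the convention that every component removed by
postprocessing was correctly rejected noise: TN = count before
postprocessing − count after; a postprocessing run that *increases* the
count violates the convention and raises rather than reporting a negative
TN. Ratios with zero denominators are reported as missing, never as 0,
to avoid silently deflating or inflating averages.

## Synthetic data

The generator emulates the color statistics the pipeline is built for:
elliptical nuclei (major semi-axis 4–9 px, aspect 0.65–1, random
orientation) with per-pixel Gaussian color noise around a dark
bluish-purple mean (60, 55, 160), over pinkish tissue background
(210, 160, 130), optionally framed by pure-white slide margin and seeded
with single-pixel nucleus-colored specks placed ≥3 px from any other
foreground. The background's blue mean sits *below* the nuclear blue so
that all three channel polarities the segmenter assumes hold in the
fixture — the defining property of the staining model being emulated. The
blue separation (30 levels) is deliberately the weakest: blue noise makes
pinholes inside nuclei, which is exactly the failure mode fill-holes
exists to repair. Nuclei are placed by rejection sampling (cap 1000
attempts per nucleus; exhaustion raises, never silently under-places), and
with overlap disallowed pairwise center distances exceed the sum of major
radii. Everything is reproducible bit-for-bit from the seed.

What the generator does not emulate: chromatin texture, defocus blur,
touching/overlapping nuclei, stain batch variation, partial nuclei at
field borders. Passing tests on these fixtures therefore demonstrates the
pipeline's correctness under its own color-polarity assumptions, not
robustness to real-slide artifacts.

## Problem sizes used in the validation suite

Oracle-equivalence checks run on ~52 random images of 5×5 to 16×16 pixels
(N=3, ε=2 and N=5, ε=5), small enough for the pure-Python nested-loop
reference. Bimodal-threshold placement uses 20 two-valued and 20
two-Gaussian 32×32/48×48 channels. End-to-end recovery uses 20 seeded
fixtures of 128×128 (≤15 nuclei) or 176×176 (up to 30 nuclei) with 3–10
specks and noise sd drawn from [5, 15]. These sizes exercise every code
path while keeping the whole suite fast; the pipeline itself runs
comfortably on full-frame microscopy images.

## Known limitations

- One global threshold per channel: fields with strong stain gradients
  need tiling or the `apply_on_enhanced` mode.
- Touching nuclei merge into one count (no declumping by design).
- The TN convention credits *all* removed components as correct
  rejections; it cannot detect a postprocessing step that removes true
  nuclei.
- The product-form histogram discards the intensity–similarity coupling;
  the joint option restores it but has no validated default advantage.
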