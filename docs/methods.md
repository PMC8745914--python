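# Methods

## Pipeline overview

One analysis consumes an image pair: a radiometric thermal matrix (°C) and
an RGB photograph of the same wound scene. The stages are

1. optional lens-distortion correction per modality (Brown–Conrady model
   under pinhole intrinsics, applied immediately after load);
2. skin segmentation per modality;
3. wound segmentation in the visual modality, confined to the visual skin
   mask, with a user review step;
4. the four IPI parameters and their weighted sum.

The two modalities come from physically separate cameras. The package
performs no cross-modal registration: masks derived in one modality are
applied to the other after dimension matching (nearest-neighbour resampling
of the smaller grid to the larger). The residual camera offset at bedside
distance is a few pixels, which is tolerable because every scored quantity
is a region-level statistic (means, maxima, counts of ≥10 px components),
not a per-pixel correspondence. Temperatures are only meaningful on the
thermal grid, so the thermal skin mask anchors all temperature-bearing
regions during scoring.

## Skin segmentation

Both modalities run the same scheme: initial rule → biggest connected area →
Canny edges → erosion to a core → edge-constrained region growing within the
initial mask → biggest area → opening + hole filling.

*Initial thermal rule.* Pixels with temperature ≥ min(T, 30 °C) are skin,
where T is the mean of the k = 2 k-means cluster centers of the pixel
temperatures (skin vs background; 8 seeded restarts, bit-for-bit
reproducible under `rng_seed`). The 30 °C cap protects scenes dominated by
skin/wound, where the data-driven threshold would rise above physiological
skin temperature; the cap is one-sided by design (no lower floor is applied
to T). A constant image has no threshold and raises a degenerate-input
error.

*Initial visual rule.* A pixel is skin iff its red value is weakly maximal
among (R, G, B); ties count as skin because the rule is equality with the
channel maximum.

*Edge-constrained growth.* The core is the initial mask eroded with the 3×3
square element until its area is ≤ 10 % of the original, with a stop rule
that never empties the mask (a single-pixel mask is its own core). Growth
from the core admits pixels that are in the initial mask and not Canny
edges; it is computed as breadth-first growth to the fixed point (iterated
masked dilation over an expanding bounding window), so the result is exactly
the set of admissible pixels reachable from the seeds, independent of pixel
order. Canny runs on the modality's grayscale — Rec. 601 luma for RGB,
min–max normalised temperature for thermal — with hysteresis thresholds
0.10/0.20 of the intensity range and σ = 1 px (all configurable; these are
ordinary Canny defaults). The final opening smooths the border and deletes
pixel-sized areas; holes (zero regions not touching the image border) are
filled.

Consequences asserted by tests: the final skin mask is a single connected
component and a subset of the initial mask's support.

## Wound segmentation

The green channel has the best wound/skin contrast, so candidate margins
are Canny edges of G. The cleanup that "deletes speckled pixels" is an area
opening — edge components smaller than `morph_kernel²` (9 px) are dropped —
because Canny curves are one pixel wide and a structural opening would erase
them wholesale. Edge detection is confined to the interior of the visual
skin mask (eroded 5 px): the skin/background silhouette is itself a strong,
cold G-channel edge and would otherwise displace the true wound margin.

Edges from structures inside the wound (necrosis, crusts, fluids) are warmer
than the wound margin. Each labelled edge's mean temperature is compared to
the unweighted average of all per-edge means; edges strictly warmer than
that average are discarded. The comparison is strict, so a single edge, or
ties at the average, always survive, and the globally coldest edge is never
discarded.

Each surviving edge seeds an independent region growing whose admission
condition is luma ≤ the mean luma of that edge's pixels, within the skin
mask. Using the seed's mean (rather than per-pixel seed values) makes the
condition a single scalar per region and the result order-independent.
Overlapping growths merge with lowest-label priority and are relabelled
consecutively in row-major order of each candidate's first pixel. The review
step picks labels or substitutes a manual mask; non-interactive callers get
the candidate table attached to the error when no selection is provided.

## Scoring

*Cold spots.* Search region: wound mask dilated by a disk of radius 10 px
("nearby the wound"), intersected with the skin mask. Candidate pixels are
strictly more than 2.0 °C colder than the wound mean; connected components
with 10–100 px count. The depth default (2.0 °C) and the nearby radius
(10 px) are configurable since clinical practice may tune them; the size
gate rejects single-pixel noise below and non-punctual structures above.

*Thermal margin and ΔT.* The anatomical margin (wound pixels 8-adjacent to
non-wound) is traversed in angular order around its centroid and grouped
into superpixels: consecutive pixels join while within 0.5 °C of the running
group mean, up to 50 px per group. Each superpixel seeds growth outward
(excluding the wound interior) admitting neighbours warmer than its mean
− 1.5 °C; the union, intersected with skin and stripped of wound pixels, is
the thermal wound margin — a peri-wound band ending at the 1.5 °C isotherm.
Intact skin is skin ∖ wound ∖ (margin dilated by 5 px); if that is empty
(e.g. a flat-temperature scene where the margin grows to the skin boundary)
the temperature difference is undefined and a degenerate-input error is
raised. ΔT = wound maximum − intact mean, signed: negative values score in
the < 1 °C band, consistent with the pathological-healing (necrosis)
reading of a cold wound. Band boundaries are inclusive on the benign side
(ΔT of exactly 1.0 or 2.0 scores 0).

*Distribution.* Inhomogeneous iff a strict majority of wound pixels deviates
more than 1.2 °C from the wound mean. For the concentrated criterion the
wound base is tiled into 7×7 grid superpixels clipped to the mask; adjacent
regions merge (closest pair first, deterministic) while their means differ
by < 1.5 °C, merged means being size-weighted; among final regions of
≥ 10 px, those deviating > 1.5 °C from the overall wound mean are counted,
and 1–3 such regions set the flag. Both distribution flags can contribute
simultaneously (the 9-point maximum is 4+2+1+1+1).

*Margin continuity.* Seeds are skin pixels on the outer rim of the thermal
margin; growth proceeds through skin pixels outside the margin; the flag
raises iff the growth reaches the wound base. An empty margin leaves the
wound entirely unguarded (flag 1).

All criteria are relative temperature differences, so every sub-score is
invariant under a constant temperature offset; this is asserted over the
full factorial phantom design.

## Phantoms

A phantom renders a warm skin ellipse (default 33 °C) on a cool background
(22 °C) with an off-center wound ellipse (default base 34.5 °C), i.i.d.
Gaussian sensor noise (σ = 0.04 °C, a typical bolometer sensitivity floor),
and an RGB rendering in which skin and wound are red-dominant and the
background is not. The default grid is 348×464 px, mirroring a common
thermal-camera resolution.

The peri-wound temperature profile is a ramp (0.3125 °C/px) from the wound
edge down to a moat floor 2.5 °C below the base, a flat moat, and a recovery
to the intact-skin plateau within 20 px. The moat floor sits 1 °C below the
margin criterion and ≥ 0.2 °C away from any cold-spot threshold the feature
mix can produce, so the thermal margin always ends on the ramp (isotherm at
1.5/0.3125 = 4.8 px) and the moat never fragments into countable cold
spots — it can only form one large (≫ 100 px) ring, which the size gate
excludes. Within an angular gap the profile sits at the moat floor up to the
wound edge, so no margin forms there and the outside connects to the wound
base.

Feature placement is analytic: cold spots are 13-px disks on an interior
ring of the wound ellipse; hot patches are 14×14 px squares (+3 °C), sized
to fully cover at least one 7×7 scoring tile at any alignment; fluctuation
sets ±1.6 °C offsets (balanced pairs around the mean of the unperturbed
pixels, so the wound mean is preserved exactly) on interior pixels, sized so
the configured fraction of all wound pixels deviates, with a 2-px guard band
around hot patches so no scoring tile mixes patch and fluctuating pixels.
The amplitude 1.6 °C lies above the 1.2 °C fluctuation criterion but below
the 2.0 °C cold-spot depth, keeping the two features independent.
`PhantomSpec.from_features` derives the intact-skin temperature so the
expected ΔT holds whatever other features are active (patches and
fluctuation raise the wound maximum).

What phantoms do **not** emulate: real wound texture and irregular margins,
skin-tone variation, specular highlights, perspective and pose, the actual
cross-camera offset, spatially correlated sensor noise, and partial-volume
mixing at region boundaries. Passing tests therefore demonstrate the
correctness of the algorithms under their stated assumptions, not clinical
segmentation accuracy.

## Problem sizes and budgets

The factorial design is 3 cold-spot levels × 3 ΔT bands × 2 homogeneity ×
2 concentration × 2 margin states = 72 cells at 348×464 px. With
ground-truth masks every cell recovers all sub-scores exactly; the full
automated pipeline (segmentation included) recovers the expected total in
all 72 cells at the default noise level. Region-growing operators are
checked against exhaustive flood-fill/reachability oracles on 200 random
32×48 instances each. One full scoring pass takes ≈ 0.5 s and one full
pipeline pass ≈ 1.5 s per pair on a single CPU.

## Known limitations

- The boundary traversal for margin superpixels orders pixels by polar
  angle around the boundary centroid, which is exact for star-convex wounds
  (all phantoms) but can interleave segments on strongly non-convex masks.
- The concentrated-distribution criterion depends on the 7×7 tiling origin
  for structures whose size is close to one tile; structures at least one
  tile large are detected at any alignment.
- The k-means threshold assumes a bimodal temperature histogram; scenes
  without background (all skin) rely entirely on the 30 °C cap.
- Undistortion resamples bilinearly; repeated application accumulates
  smoothing. Intrinsics estimation is out of scope — parameters are
  consumed from JSON.
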