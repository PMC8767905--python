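# Methods

## Scope and model of the experiment

The package models a controlled-environment reproductive-stage drought
screen: a cohort of near-isogenic rice lines plus two parents, grown in
saturated 18.5 kg pots under a stressed and an unstressed treatment,
imaged at five stages and weighed daily. Stage days default to
(0, 5, 10, 12, 15): stages I–III track progressive drying, the soil
reaches the irrigation-trigger moisture on day 11, lifesaving irrigation
restores saturation on day 12, and stages IV–V track recovery. The
published schedule is ambiguous between "five-day intervals" and "stage
IV two days after irrigation"; the latter is used because it is the only
one consistent with the day-11 trigger, and the stage days are
configurable.

## Latent tolerance and the synthetic cohort

Each genotype carries a scalar tolerance tau ∈ [0, 1]. NIL taus are drawn
U(0.068, 1); with the relative yield drop mapped linearly as
RDY(tau) = 0.73·(1 − tau), this puts the cohort-mean RDY at the observed
0.34 and the range inside the observed 0.0–0.73. The recurrent parent is
fixed at tau = 0.027 (RDY ≈ 0.71) and the donor parent at tau = 0.33
(RDY ≈ 0.49), their published values. Unstressed yield is uniform on
7.5–14 g/plant, the pot-trial scale; stressed yield is
Yp·(1 − RDY(tau)) + N(0, 0.5 g), clamped to [0, Yp].

Trait trajectories are anchored at cohort means taken from glasshouse
observation: stressed TR 0.072 → 0.036 → 0.063 g/cm²/day and stressed NIR
167.56 → 185.62 → 180.54 gray at stages I/III/V; unstressed NIR drifts
166.81 → 180.7 with maturity while unstressed PSA/WU/TR stay flat.
Per-genotype heterogeneity multiplies the mean decline by
(1 ± 0.8·(tau − tau̅)): PSA shrinkage and NIR brightening grow with
(1 − tau) (damage), WU and TR reduction grow with tau (water saving —
the response pattern tolerant lines show), and the recovered fraction of
the stage-III deficit grows with tau (spread 0.6, mean 0.75 for TR and
0.28 for NIR from the anchors; 0.6 for PSA and WU, a free choice).
Because decline and recovery spreads are centered on the cohort mean,
stage-anchor means are preserved exactly in expectation up to a small
tau-covariance term (< 2 % of the anchor; inside every stated tolerance).
Stage II and IV values interpolate the I–III–V knots linearly in days.
WU is generated as its own trait (base 3.0 ml/g/day, decline range
44–76.1 %) rather than derived from TR: WU normalizes by biomass and TR
by area, and the two observed decline ranges differ, so locking them
algebraically would contradict one anchor or the other.

Noise defaults (PSA 15 cm², WU 0.08 ml/g/day, TR 0.002 g/cm², NIR 1.5
gray, yield 0.5 g) are free parameters: the source reports cohort means
but no per-plant variances. They are set so that stage contrasts remain
significant while rank recovery is imperfect — the regime the analysis
is meant to operate in.

## Pot-water budget

A saturated pot is tare 1,000 g + dry soil 14,000 g + water 3,500 g,
giving 25 % gravimetric soil moisture (w/w) at saturation and 12 % —
the lifesaving-irrigation trigger, half of saturation — after 1,820 g of
cumulative loss. Mass-based SMC is used throughout because pot weight is
the only measured quantity (the "25 % w/v" phrasing in the source is
internally inconsistent with gravimetric determination). Daily plant
transpiration is TR·PSA interpolated onto days, holding the stage-III
value through day 11; evaporation is a shared per-treatment daily draw
(CV 5 %) whose base is set inside the generator so the cohort-median
cumulative loss on day 11 equals the 1,840 g depletion at which severe
stress was observed — making trigger day 11 / irrigation day 12 emerge
from the soil physics rather than being stamped on. Mock pots lose only
evaporation plus N(0, 2 g) per-pot noise, so recovered transpiration is
exact up to the mock-noise envelope. Weights are exact cumulative sums:
water balance (Σ ET = initial − final + Σ irrigation) holds to float
precision, and tests assert it.

## Imaging

Segmentation thresholds the excess-green index 2G − R − B with Otsu's
method, requires genuinely positive excess green (so gray-level
background changes cannot segment), and removes 8-connected components
under 25 px. PSA is the mean (configurable to sum) of the three
side-view areas; the mean keeps the estimate on a single-view scale and
is stable under view permutation. The top view feeds only the
projected-plant-area growth rate. NIR→RGB registration is a linear
least-squares affine on paired control points (≥ 3, non-collinear
required); the mean NIR gray is read by mapping NIR pixel centers into
the RGB frame with nearest-pixel mask lookup — gray values are never
resampled, since interpolation would bias the hydration score near the
silhouette boundary.

The renderer draws tillers as tapering polygon strokes whose count and
length scale with the area target (stroke width stays near 3 px so thin
strokes neither vanish nor fragment) and bisects a global width
multiplier until the rasterized silhouette hits the requested area
within 1 %; leaf rolling narrows strokes and increases their number.
Canvases are 640×640 RGB and 320×320 NIR with a known scale-2 affine
plus small offset, exercising the resolution-mismatch registration at a
size that renders in milliseconds. What the renderer does not emulate:
occlusion by the pot, specular leaves, uneven illumination, soil pixels
with positive excess green. Passing round-trip tests therefore validate
the extraction arithmetic and registration chain, not segmentation
robustness on real glasshouse imagery.

## Indices and table reproduction

Grand means include every row of the supplied table (parents included):
recomputed SSI/STI then match the published per-genotype values. TOL is
computed both as Yp − Ys in grams (`TOL_diff`, the form every published
per-genotype value uses) and as a percentage of Yp (`TOL_pct`, the form
the index's definition table prints); the gram form is the default for
rankings and comparisons. Check comparisons are strict (ties never count
as better) and run in each index's tolerance direction; for the one
published count that hinges on the source's own 1-dp rounding (TOL vs
the donor parent, a printed tie at 7.2), the comparison can be made on a
printed column instead of recomputed values. A genotype missing either
yield is dropped from grand means with a warning, never imputed.

Three printed cells are not reproducible from their own printed yields
and are reported as mismatches rather than matched: both parents' RT in
the pot table (consistent only with unrounded stressed yields) and one
NIL's YI in the field table (prints 0.9, recomputes 0.81). Published
correlation tables between traits and yield are *not* reproduced
numerically — they require the unavailable per-plant raw data — only the
correlation machinery (per-cell Pearson r with two-sided t-test flags at
α = 0.05, no multiplicity correction, mirroring the source's starring)
is provided.

## Selection score

Five rank components (smallest |PSA decline|, smallest NIR rise, largest
WU reduction, largest TR reduction, fastest III→V PSA gain) are averaged
unweighted — the source states the desirable pattern but no weights.
Ranks use average tie-handling over NILs and checks jointly, and the top
k = 9 composite ranks are flagged selected. Recovery speed as the raw
III→V percent gain can run against tau (a small decline leaves little to
regain); with four of five components aligned the composite ordering is
still exactly monotone in tau at zero noise, and recovers the latent
ordering at Spearman ≥ 0.8 under default noise.

## Problem sizes and determinism

Defaults: 35 NILs + 2 parents, 2 treatments, 5 stages, 16 days of pot
weights, 4 mock pots per treatment, images rendered for a 2-genotype
subset at three stages (rendering is a validation artifact, so the
default keeps the full run in seconds; any subset size is configurable).
All randomness flows from one integer seed through per-stage hashed
substreams, so identical configurations give byte-identical CSVs; the
pipeline manifest content-addresses every output.

## Known limitations

Trait trajectories are piecewise-linear in stage knots — no diurnal or
weather structure; evaporation is treatment-shared, not pot-specific;
the tau→trait maps are linear with additive Gaussian noise, the simplest
family satisfying the monotonicity the analysis assumes; field soil
physics (tensiometer dynamics) and the agronomic/grain-quality traits of
the source trial are out of scope.
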