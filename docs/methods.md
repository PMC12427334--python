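# Methods

This note documents the models, numerical choices and limitations of
`pigcycle`, module by module, in the order data flows through the loop.

## Synthetic data

The generators stand in for three farm data sources that are never
published: dorsal camera footage, per-animal scale records, and the farm's
activity ledgers. Each is built so the downstream stage has a known
answer to recover.

**Silhouettes.** A dorsal mask is modelled as a superellipse
|x/a|ⁿ + |y/b|ⁿ = 1 (n = 2 is an ellipse; pig backs are squarer, n ≈ 2–3),
rotated, optionally perturbed radially by a low-order Fourier series whose
pointwise SD is the `boundary_noise_sd` parameter, and rasterised by
pixel-centre inclusion. Closed forms travel with the raster: area
4ab·Γ(1+1/n)²/Γ(1+2/n), axes 2a/2b, eccentricity √(1−(b/a)²). Pixel-centre
rasterisation has first-order boundary error; the suite verifies that
doubling resolution at least halves the relative area error (averaged over
sub-pixel placements, because the signed error oscillates with lattice
alignment). Not modelled: perspective, posture, occlusion, multi-animal
scenes — a mask here is always one clean silhouette, so passing tests
bound geometric error only, not segmentation error.

**Growth cohorts.** Default conditions are a single-farm full-cycle
trial: 63 pigs of three breeds (Landrace 40%, Jinfen White 25%, Duroc
35%), start weights uniform in 6–25 kg, 150 days, per-pig ADG ~
N(0.65, 0.05²) kg/day held constant over the cycle (growth is modelled as
linear because ADG is the statistic the feeding rules consume; a Gompertz
curve would add parameters nothing downstream uses), weights capped at
125 kg (market plateau). Weigh-ins carry additive N(0, σ²) noise
(σ = 0.5 kg for scale-grade records, 3 kg in the recovery experiments to
emulate image-based estimation error); cadence is every 3 days below 30 kg
and every 7 days above, mirroring piglet vs finishing monitoring
practice.

Features link to weight through fixed isometric allometry — RA =
0.0139·W^(2/3), CP = 160·W^(1/3), BL = 68·W^(1/3), BW = 34·W^(1/3) (pixel
units on a 640 px frame), each with ~4% multiplicative noise, and E drawn
independently on [0.21, 0.79] because eccentricity carries almost no
weight signal in practice. The exponents are generator-internal ground
truth, not claims about pig biology; the RA coefficient places the
frame fraction inside the 0.10–0.50 span observed on real dorsal imagery
over the fattening range. `silhouette_for_weight` inverts the allometry
into a renderable shape; because area and frame fraction share the W^(2/3)
scaling, one frame size (≈360 px) makes rendered-mask RA agree with the
tabulated RA at every weight.

**Ledgers.** Feed tonnage = cohort live-weight gain × FCR 2.8, split
63/16/12/9% corn/soybean-meal/wheat-bran/compound (the farm-average mix);
manure nitrogen and mass follow per-breed head-day excretion (26–33 g
N/day, 2.8–3.8 kg manure/day); energy draw 40–80 kWh plus 2–4 kg diesel
per head-cycle, chosen so the feed chain is the dominant footprint
component as on real fattening units; two transport legs (feed inbound,
pigs outbound). Manure defaults to 60% anaerobic digestion / 40%
intensive-turned composting; the split must be stated because the two
systems sit at opposite ends of the N₂O factor table.

## Morphometrics

Preprocessing: closing with a disc (default radius 3 px — the kernel any
smaller fails to bridge typical segmentation dropouts, any larger begins
rounding the silhouette), hole filling, largest 8-connected component.
An empty result is an error naming the input.

Contours are traced by marching squares on the binary grid after a mild
Gaussian blur (σ = 1 px). The blur exists for a numerical reason: the 0.5
level set of raw binary data is a staircase polygon whose arc length
overestimates a smooth boundary by ≈5%, while the level set of the blurred
field tracks analytic ellipses and rectangles to a few tenths of a percent
and does not shift the boundary (a symmetric blur leaves the 0.5 crossing
at the edge). The minimum-area rectangle comes from rotating calipers
over the contour's convex hull; the ellipse fit is a direct least-squares
conic on up to 400 subsampled contour points; a non-elliptical fit is a
hard error.

Eccentricity is reported as √(1−(b/a)²). Printed sources sometimes give
the non-radical 1−(b/a)² under the same name; both are compatible with the
observed 0.21–0.79 range, the radical form is the standard definition and
the default, and `squared_variant=True` selects the other.

Units are pixels unless a physical scale (length/pixel) is attached, in
which case CP, BL, BW scale by it and RA, E are unchanged (verified as a
property). No camera calibration is assumed, so published centimetre
feature statistics are not reproduction targets.

## Weight model

Forest regression with strictly animal-level partitioning: the 80/20
split rounds 20% of pig IDs to the nearest whole pig (63 → 13 test pigs),
and the 5 CV folds are round-robin over shuffled pig IDs. Extending the
pig-level rule from the outer split into the folds is the only
leakage-consistent reading of the protocol. Grid-search ties are broken
toward the smaller forest, then the shallower depth, then the larger
min-split — parsimony, and it makes the winner deterministic. The seed is
explicit everywhere; a failed grid cell is recorded and skipped.

The recovery experiment (63 pigs, 3 kg weigh-in noise, default allometry)
reaches held-out R² ≈ 0.98, MAE ≈ 3.6 kg against a 3 kg noise floor, and
ranks RA first with ~98% of importance — higher than the ~35% seen on
real farms, because the synthetic RA–weight link is far cleaner than real
segmentation allows. The test asserts rank and R², not the share. The
default analysis grid is the 8-cell `SearchGrid.small()`; the full
48-cell protocol grid is available (`--full-grid`) and changes nothing
qualitative on synthetic data.

## Feeding rules

The printed stage boundaries leave 0.1 kg gaps (15.0→15.1, 40.0→40.1,
80.0→80.1); the table uses half-open intervals centred on the gaps
([7.0, 15.05), [15.05, 40.05), [40.05, 80.05), [80.05, ∞)) so every
positive weight maps to exactly one stage. Weights under 7 kg map to the
weaning stage with a warning. Weaning feeding frequency is 7 meals/day
(midpoint of the stated 6–8).

The slow-grower band target "18–20%" soybean meal defaults to its midpoint
19% (configurable). Re-balancing after an adjustment is pro-rata over the
two filler ingredients (wheat bran, compound-and-concentrate), preserving
their relative mix; if a target combination exceeds 100% the fillers clamp
at zero and the residual is absorbed by the largest adjusted component,
with a flag. Rule precedence — the slow-grower correction overrides the
growth-band rule — follows from its corrective intent. Both choices keep
the operation idempotent, which the suite checks over randomized rations.

ADG is the OLS slope of weight on day over a trailing 14-day window
(falling back to all records if the window holds fewer than two points);
two observations reduce to the finite difference. Daily feed quantity has
no published closed form ("reduce when gain accelerates" is qualitative),
so `plan_feed_quantity` is an explicit extension point: a piecewise-linear
allowance curve in configuration, interpolated and clamped at its end
knots, scaled by reference/actual energy density (reference 12 MJ/kg).

## Carbon accounting

All five components return kg CO₂-eq and are linear (degree-1
homogeneous, additive over merged ledgers); the suite checks this over
randomized ledgers because linearity is what makes scenario comparison
well-posed.

Numerical and interpretive choices:

- Transport factors (0.185/0.197/0.321 kg CO₂-eq by vehicle class) are
  applied per tonne-km — the only dimensionally coherent reading of a
  distance × tonnage product.
- All N₂O-N flows convert to N₂O mass by 44/28 before GWP weighting (IPCC
  convention).
- The manure CH₄ term uses GWP_CH₄. One printed rendering of the manure
  equation attaches GWP_N₂O to the CH₄ term; `strict_printed_manure_gwp`
  reproduces that variant for comparison, the default follows the
  dimensionally consistent reading.
- Manure CH₄ per kg N defaults to 0.005 (upper end of the stated 0–0.005
  range); the indirect leaching factor 0.0075 kg N₂O-N/kg N is an
  IPCC-style default supplied by this package, both configurable.
- The enteric baseline is 1.00 kg CH₄/head/yr at the 105 kg reference
  weight, scaling linearly with average body weight; a 1.5 value also
  circulates and is accepted as configuration.
- Feed-chain emissions default to aggregate per-kg factors (corn 0.37,
  soybean meal 0.11, wheat bran 0.26 kg CO₂-eq/kg — soybean meal below
  corn is unusual but used as given; compound feed is assigned corn's
  factor absent a published value). The detailed cultivation pathway
  (fertilizer production, field N₂O, urea, pesticide, film, irrigation,
  machinery fuel, processing energy with energy-content by-product
  allocation) requires per-crop yields and input rates the user must
  supply, since no published set exists.
- The factor set validates at load: negative factors, fraction rates
  above 1, or an electricity factor that looks like kg/MWh instead of
  t/MWh are hard errors.

SEM = SD/√n (sample SD) is provided for reporting per-pig footprint
spreads.

## Problem sizes and determinism

Default experiment sizes — 63 pigs × ~27 weigh-ins, 20–40 rendered
640 px (or 360 px) masks, 100 randomized ledgers, 1000 randomized rations
— were chosen as the smallest sets at which the checked statistics are
stable across seeds. Every random draw flows from an explicit integer
seed through `numpy.random.default_rng`; the pipeline manifest hashes all
artifacts so cross-run drift is detectable.

## Limitations

- Synthetic masks bound geometric error, not segmentation error; no
  statement about accuracy on real footage follows from these tests.
- The allometric feature link is an idealisation; real feature–weight
  relations vary by breed, posture and camera geometry.
- The feeding module encodes the ration rules, not nutritional adequacy;
  it does not model the biological response to a ration change, so
  scenario comparisons take both footprints as inputs rather than
  predicting the optimized one.
- The LCA is cradle-to-farm-gate only: no post-farm stages, no water
  footprint, no uncertainty propagation beyond SEM.
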