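# Methods

This note documents the models, conventions and numerical choices
behind `vmatqa`, in the order data flows through the package.

## Plan model and segment dynamics

A VMAT plan is a list of arc beams, each a sequence of control points
carrying gantry angle (deg, [0, 360)), cumulative meterset weight
(normalized so the last control point is 1), the two MLC bank position
arrays and four jaw positions. Coordinates are IEC 61217, mm projected
to isocenter; bank A is the X1-side bank, bank B the X2-side; the
leaf-pair index runs from the most negative y. Two 60-pair Varian MLC
profiles are built in (HD: 14×5 / 32×2.5 / 14×5 mm; Millennium:
10×10 / 40×5 / 10×10 mm). Gantry angles are unwrapped around the
0°/360° seam using the beam's rotation direction before differencing,
so a clockwise 181° → 179° two-point beam spans 358°.

Dose rate and gantry speed are not stored in RT Plans. They are
reconstructed per segment with the standard maximum-constraint model:
the segment duration is the longer of the MU delivery and the gantry
rotation,

    dt_k = max(dMU_k / DRmax, dtheta_k / GSmax),

so every segment with motion or MU saturates at least one machine
limit — the usual convention for control-point-sampled dynamic arcs.
Default limits: DRmax 600 MU/min for flattened beams, 1400 MU/min for
6 MV FFF, 2400 MU/min for 10 MV FFF; GSmax 4.8 deg/s. These are
commissioning-style assumptions, not values stated with the metric
definitions, and are overridable per machine.

## Aperture geometry

Per control point, each leaf pair contributes the x interval
[max(bankA, jawX1), min(bankB, jawX2)] over its leaf span clipped to
the Y jaws. Pairs whose clipped gap is ≤ `min_gap` (default 0.5 mm,
the dynamic-leaf-gap/closed-pair convention) or with no y overlap are
excluded. Aperture area is the summed rectangle area. The perimeter is
the boundary length of the rectangle union: leaf-end edges contribute
twice each pair's height; horizontal edges contribute the symmetric
difference of x intervals between y-adjacent open pairs, plus full
extents at the top and bottom of each maximal run of open pairs — so
stacked identical intervals merge seamlessly and disjoint openings
bound separate polygons. Both quantities are verified in the test
suite against an independent rasterization/edge-walking oracle on
grids aligned to every breakpoint, where the formulas are exact.
Aperture irregularity is the isoperimetric ratio AP²/(4π·AA): exactly
1 for a circle, 4/π for a single square opening, and ≥ 4/π for any
rectilinear aperture.

Aggregation conventions (the metric definitions do not pin these down;
each is covered by an identity test):

- Each control point is weighted by the MU of the segment *following*
  it; the final control point carries zero weight. A constant-aperture
  beam therefore reproduces its own AA and AI as BA and BI.
- BI is the MU-weighted mean of per-control-point AI, not the AI of a
  mean shape (the convention of the metric's source literature).
- Control points with fully closed apertures contribute zero area to
  BA and are excluded (weights renormalized) from BI; a beam closed at
  every MU-carrying control point has undefined aggregates.
- Plan-level LT/AL, DR variation and GS variation aggregate over beams
  with beam-MU weights, mirroring the PA/PI rule, since the published
  definitions are silent for multi-arc plans.

Leaf travel: a leaf participates if its pair is open (after jaw
clipping) at any control point of the beam; both leaves of a
participating pair are counted individually, and LT is the mean of
their per-arc travel distances. The alternative convention that
averages over all 120 leaves is available via
`leaf_travel_per_al(..., participation="all")`. DR/GS variation sums
run over consecutive *derived segments* (control-point differences),
the natural reading for quantities that only exist per segment.

## Synthetic cohorts

The generator emulates the structure of a clinical VMAT QA program
without any clinical data. Four archetypes fix the machine, energy,
number of arcs, characteristic target radius, shape irregularity, leaf
modulation and MU range:

| archetype | machine | energy | arcs | radius (mm) | irregularity (mm) | modulation (mm) | MU |
|---|---|---|---|---|---|---|---|
| IMRS | HD | 6FFF | 3 | 9 | 2.8 | 1.1 | 1800–3200 |
| HN | Millennium | 6FFF | 2 | 22 | 1.5 | 1.0 | 450–750 |
| MED_LUNG | Millennium | 6X | 2 | 17 | 1.1 | 0.9 | 420–900 |
| PROSTATE | Millennium | 10X | 1 | 30 | 0.6 | 0.8 | 580–680 |

Leaf openings trace a multi-lobed ellipse whose center sways
sinusoidally across the arc (a stand-in for beam's-eye-view parallax);
static per-leaf noise sets shape raggedness, a smooth AR(1) per-leaf
jitter sets control-point-to-control-point modulation, and the sway
amplitude scales with √modulation so frozen-leaf configurations
(modulation = irregularity = 0) have exactly zero leaf travel.
Meterset increments are smooth positive AR(1) weights whose relative
SD (`meterset_roughness`) is drawn independently per plan — this is
what gives dose-rate variation a life of its own instead of being a
proxy for total MU. Arcs are sampled every 2°, the common control-point
spacing for optimized VMAT plans. The default cohort mix is 40 IMRS /
25 HN / 28 mediastinum-lung / 25 prostate, scaled proportionally for
other cohort sizes. Everything is deterministic given (spec, seed).

These choices reproduce the qualitative clinical pattern: radiosurgery
plans have the smallest, most irregular apertures and the highest MU
and dose-rate variation; prostate plans the largest and roundest
apertures, the tightest MU distribution and (being flattened-beam,
single-arc) the largest gantry-speed variation.

Simulated GPR is a clipped linear-Gaussian model on cohort-z-scored
features: g = clip(95 + Σ βⱼzⱼ + ε, 80, 100), ε ~ N(0, 1). This is a
calibration device, not physics: the coefficients were fitted once, by
sign-constrained fixed-point iteration on a 2000-plan default cohort,
so that the empirical feature–GPR Pearson correlations match published
clinical values (PA +0.723, PI −0.672, MU −0.660, GS +0.624, DR
−0.497, LT/AL −0.382), and then frozen as package defaults (β = 0.392,
−0.259, −0.503, −0.588, −0.298, 0.917 in that order). On independent
500-plan cohorts the six correlations land within ±0.09 of those
targets, with ~99% of GPRs in the (90, 100] band and under 2% clipped
at 100. A feasibility analysis drove two generator design points: the
target correlation vector is only attainable if the feature
correlation matrix is not dominated by a single site axis, hence the
independent per-plan meterset roughness and the variable sway
amplitude.

What passing tests on this cohort do *not* show: the generator has no
dose calculation, no delivery-error model, no detector geometry, and
its GPR has no physical meaning — agreement of the pipeline with the
generative model demonstrates the statistical machinery, not clinical
predictive validity.

## GPR regression

Measured GPRs concentrate in (90, 100)%, the flat tail of the logit
curve, and a linear SVR fitted to raw percentages can predict values
above 100%. The remedy is a rescaled logit: divide by 100, subtract
0.9 (flooring negative results at zero), multiply by 10, then apply
logit. Predictions are inverse-transformed, which bounds them to
(90, 100). The floor makes logit(0) appear for GPRs at or below 90%,
so the rescaled argument is clipped to [ε, 1−ε] with ε = 1e-3 — a
well-posedness deviation from the set-to-zero rule, documented here.
By default the transform applies to the SVR only: a regression forest
cannot extrapolate beyond its training targets and needs no bounding
("both" and "none" are selectable).

Models are scikit-learn's RandomForestRegressor (150 trees, min leaf
6, min split 3, √p features, max depth 80) and linear-kernel SVR
(C = 1, ε = 0.5). SVR features are z-scored by training statistics
(C is scale-sensitive); the forest sees raw features. A grid-search
tuning routine with 10-fold CV is provided but the defaults pin the
values above. Evaluation is 30 shuffled 70/30 splits; MAE, RMSE and R²
are computed per split on the GPR percentage scale and summarized as
mean ± SD (R² per split, not pooled), plus the overall maximum
absolute error and the fraction of test predictions within 3
percentage points. Permutation importance is scikit-learn's, scored as
mean R² decrease on the percentage scale. Correlation strength bands
are half-open on |r|: none ≤ 0.2 < weak ≤ 0.4 < moderate ≤ 0.6 <
strong < 0.8 ≤ very strong (the published band edges leave small gaps;
boundaries resolve downward except 0.8, which the source defines as
opening "very strong").

One measured limitation, established during design: with the fixed
ε = 0.5 tube, a linear SVR cannot recover a noiseless linear law
perfectly — the ε-insensitive loss tolerates slope shrinkage worth
roughly 1–2% of R² even on ideal features, and the logit warp (the
generative model is linear on the percent scale, the SVR then fits on
a curved one) costs several points more. The packaged
parameter-recovery check therefore assesses recovery on the
untransformed scale (`apply_to="none"`), where the noiseless test R²
exceeds 0.98; the transform's job is bounding, not linearization.

## Delivery-log checking

Percent error between expected and delivered machine parameters is
(actual − expected)/expected × 100 per sample, reported as the maximum
absolute error per parameter and optionally per site, with the
achieving sample index for audit. Samples with expected exactly zero
(gantry at 0°, a jaw at 0 mm) are undefined and are flagged and
counted, never silently zeroed or included in maxima. Angles are
compared after shifting the actual value to the representative nearest
the expected one, so 359.9° vs 0.1° is a 0.2° discrepancy. Binary
vendor log parsing is out of scope; input is a plain CSV of paired
samples.

## Problem sizes and determinism

Packaged checks use cohorts of 118 (the default mix), 200 (recovery)
and 500 plans (calibration and hold-out floor), sizes at which the
statistics of interest are stable while a full run of the suite plus
the acceptance script stays around a minute of compute. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (configuration, seed) pairs
yield byte-identical cohorts and bit-reproducible evaluation
summaries.
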