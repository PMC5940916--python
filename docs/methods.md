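# Methods

This note documents the models, algorithms and defaults of `grainsdm`, and
what the synthetic experiments do and do not demonstrate.

## Raster geometry

Coordinates are planar metres without a CRS: the study design is
grain-relative, so georeferencing adds nothing at desk scale. The origin is
the outer corner of the upper-left cell and the row index increases
southward. I/O is Esri ASCII grid with a bit-faithful round trip (`%.17g`).

**Resampling** evaluates at target cell centres — the GIS convention for
the two named methods — not block averaging. Continuous layers use
bilinear interpolation over the four surrounding source centres (clamped
at edges); categorical layers use nearest neighbour with a deterministic
tie-break (smallest row, then smallest column). Nodata propagates from any
source cell with positive interpolation weight; zero-weight neighbours are
ignored so that resampling at the native grain is an exact identity. The
output extent is truncated to whole target cells anchored at the origin.

**Slope and aspect** come from Horn's 3×3 finite differences with edge
replication. Slope is degrees from horizontal; aspect is degrees clockwise
from grid north pointing downslope, with flat cells set to nodata (no
meaningful orientation). Aspect handling downstream is switchable:
`aspect_mode="degrees"` feeds raw degrees to the model;
`aspect_mode="northness"` replaces aspect by cos(aspect) *before* any
resampling. The pipeline defaults to northness because (a) bilinear
interpolation across the 0°/360° wrap invents south-facing values between
two north-facing cells, and (b) a linear+quadratic feature basis cannot
represent a function that must agree at 0° and 360°. Raw degrees remain
available and are exercised in the tests.

**Distance to water channels** is the exact Euclidean distance transform
(scipy's EDT, cell centres, metres), verified in the tests against a
brute-force nearest-source scan.

## Synthetic landscapes and the virtual species

The generator emulates an upland-UK style study region. Defaults (chosen
once, as plausible field values):

| parameter | default | meaning |
|---|---|---|
| extent_cells | 200×200 | 10×10 km at the native 50 m grain |
| terrain_relief | 900 m | sea level to ~900 m over short distances |
| terrain_corr_length | 1500 m | ridge/valley scale of the random field |
| n_landcover_classes | 5 | thresholded altitude × random-field mixture |
| channel_density | 0.002 | ~80 channel sources per landscape |
| climate_corr_length | 5000 m | climate varies only at multi-km scale |

Terrain is white noise filtered with a Gaussian kernel of the stated
correlation length, rescaled to the relief; zero relief is rejected as
degenerate. Land cover thresholds the rank-mixture
`w·rank(altitude) + (1−w)·rank(independent field)` at equal quantiles, so
every class is present and spatially coherent and correlated with
altitude. Channels are traced by steepest descent from random source cells
until the grid edge or a pit (no hydrological pit-filling). The two
climate surfaces are smooth random fields scaled to temperature-like and
precipitation-like units; they carry no information about the virtual
species, which is the point: they stand for predictors that force a coarse
grain without adding specialist signal. The transfer landscape uses a new
seed, 65% of the training relief and a land-cover mixture shifted by 0.15
— "same generator, different topographic character".

The virtual species is a habitat specialist with true suitability

    S = logistic( amp·exp(−((alt−opt)/tol)²/2) + slope_coef·z(slope)
                  + northness_coef·cos(aspect) − water_decay·d_water
                  + bonus·1[landcover = preferred] )

with defaults amp = 2, opt = 150 m, tol = 120 m, slope_coef = −0.5,
northness_coef = +0.5, water_decay = 0.002 m⁻¹, bonus = 1.5 for the
woodland-analogue class: a low-altitude, shallow-slope, north-facing,
near-water woodland specialist. Flat cells contribute a neutral northness
of 0. Presences (default 152 training, 100 transfer, matching the study's
sample sizes) are drawn per cell proportionally to S and jittered
uniformly within the cell, which avoids lattice artifacts in rarefaction.

What the generator does *not* emulate: sampling bias, positional error in
occurrence records, biotic interactions, temporal dynamics, anisotropic
terrain, and real hydrology. Passing tests therefore show that the
pipeline behaves correctly *when its assumptions hold*, not that any
particular grain is best for real survey data.

## Variable sets and collinearity

VS-1 (1 km) is the climate surfaces plus all biophysical layers resampled
to 1 km; VS-2 (300 m) and VS-3 (50 m) are biophysical only. The Pearson
screen is computed at 10,000 background points rather than on raster cells
so that the screen's sample size does not change with grain. Absolute
correlation is screened even though the convention is often quoted as
"r ≤ 0.70": strong negative collinearity is equally harmful. Elimination
is greedy — repeatedly find the worst pair above the cutoff and drop the
member with the larger mean |r| against the remaining layers, breaking
ties alphabetically; operating on sorted names makes the result
independent of layer listing. Categorical land cover is excluded from the
screen (Pearson is undefined on class codes) and always retained.

## The maximum-entropy model

Feature classes are restricted to linear + quadratic terms and categorical
indicators — no hinge, threshold or product features. This keeps the
objective small and strictly convex, every test interpretable, and the
coefficients identifiable; it is a deliberate reduction relative to the
auto-feature behaviour of the classic MaxEnt software. Continuous features
are standardised by background mean/sd. The per-feature L1 weight is
`reg_beta · sd_bg(f_j) / √m` (default reg_beta = 1.0), i.e. constant
features are never penalised into mattering and the penalty vanishes at
large presence samples.

Optimisation splits λ into positive and negative parts, turning the L1
term into a linear objective over a non-negative orthant, and runs
L-BFGS-B. The regularised gain is recorded every iteration; fitting stops
when the gain improves by less than `tol` (default 10⁻⁶, budget 5000
iterations). Concavity makes the trajectory non-decreasing, which the test
suite asserts on every fit it makes. The tolerance is interpreted as gain
change per iteration; tests that need coefficients to many digits pass a
tighter `tol`.

Outputs: raw = normalised Gibbs density over the evaluated cells
(re-normalised over each projection area), logistic =
e^H·raw/(1 + e^H·raw) with H the training-background entropy; pointwise
scores use the equivalent form sigmoid(H + λ·f − log Z_train). Clamping
truncates each expanded feature to its training min/max. Fade-by-clamping
has no published closed form; it is implemented here as
`max(0, logistic_clamped − |logistic_clamped − logistic_unclamped|)`, with
a clamp-flag grid marking every affected cell so users can see exactly
where attenuation applied.

Replicates follow the study defaults: 25 bootstrap runs (5 in the reduced
test/acceptance configurations), each a 75/25 partition of the rarefied
presences. "Bootstrap" is implemented literally as a partition without
replacement, following the stated 75%/25% allocation; a with-replacement
mode exists behind a flag. A fresh set of background points is drawn per
replicate. Rarefaction keeps the *first* point per cell (input order)
rather than a random one, saving a seed while staying deterministic.

## Evaluation

AUC is the exact Mann-Whitney statistic (ties ½) of presence scores
against the replicate's background sample — background as pseudo-absence,
since the design has no true absences. This bounds attainable AUC well
below 1 for a wide-niche species; AUC values here are comparable across
grains, not against presence/absence studies.

The Boyce index bins the logistic map (default 10 equal-width classes;
rank-quantile binning available, and used for the monotone-invariance
property test) or slides a window of 1/10 of the suitability range in 100
steps (the continuous mode — the headline metric). P = share of presences
per class, E = share of cells per class; classes with E = 0 have undefined
P/E and are excluded from the Spearman correlation, whose one-tailed
p-value uses the large-sample t approximation.

Permutation importance permutes one raw variable across the combined
presence+background rows, re-expands features, and records the AUC drop,
normalised to 100% — an AUC-drop definition, chosen because the classic
software's internal variant is not documented. Response curves sweep one
variable across its training range with the others at background means
(categorical at the modal class).

Transfer scoring projects every replicate with fade-by-clamping, averages
the maps, rarefies the transfer presences at the active grain (symmetry
with training), and computes the CBI of the *mean* map — one CBI per
scenario. Scoring across grains is a hard error rather than a silent
resample. The reported clamp fraction is the mean over replicates of the
share of valid cells with any clamped feature.

## Diagnostics on synthetic data

Two simulation-based checks deserve a note on their design:

- **Sign recovery.** The virtual species has slope_coef < 0 and
  northness_coef > 0; the check asks whether the fitted linear λ for slope
  and northness recover those signs across seeds. The diagnostic fits
  *linear-only, unregularised* models: with a quadratic term present a
  monotone decreasing response can be represented with a positive linear
  coefficient, and the L1 penalty truncates weak coefficients to exactly
  zero — in both cases the sign of the linear λ is simply not the
  estimand. Under the identifiable design, recovery is essentially
  deterministic.
- **Grain ordering.** The training-area check runs the full pipeline at
  200×200 native cells with 5 replicates per scenario across 10 master
  seeds and asks for test AUC ordered 50 m ≥ 300 m ≥ 1 km in at least
  8 of 10 — an ordering, not an effect size, because per-seed AUC
  differences between 50 m and 300 m are small relative to replicate
  noise. Transfer CBI by grain is reported but not asserted: which grain
  transfers best genuinely depends on how the two landscapes differ, and
  the mid-grain advantage is a tendency, not an invariant.

Problem sizes in the test suite and acceptance script (80–200 cells per
side, 400–10,000 background points, 1–5 replicates) are reduced from the
full study defaults; they were chosen so the whole suite completes in well
under a minute while every statistical check retains comfortable margins.

## Known limitations

- No hinge/threshold/product features; very sharp true responses would be
  underfit relative to the classic software.
- The logistic output's entropy constant is estimated on background
  points while projection re-normalises over all cells; ranks (and hence
  AUC and Boyce) are unaffected, but absolute logistic values should not
  be compared across differently sized projection areas.
- Aspect in raw degrees interacts badly with bilinear resampling and
  polynomial features (see above); northness is the recommended mode.
- Channel tracing stops at pits; the water-distance layer is not a
  hydrologically corrected drainage network.
- The Pearson screen is pairwise only; no VIF or other joint diagnostics.
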