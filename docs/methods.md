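# Methods

This note records the models implemented, the numerical choices made
where the design was genuinely open, and what the synthetic data can
and cannot tell you about real surveys.

## Terrain metrics on elevation grids

A reef plot is a raster of substrate heights on square cells (default
cell size 1.0 cm, the standard fine-scale resolution for reef
photogrammetry; configurable).  All metrics share one boundary/nodata
policy: any quantity needing a 3×3 window is undefined (masked) where
the window is incomplete, and plot means exclude undefined cells.  No
padding or interpolation is invented at edges — that would manufacture
substrate.

**Surface rugosity.**  The 3D area is the sum of two triangle areas per
quad of adjacent cell centres, each quad split along its NW–SE
diagonal, restricted to quads whose four corners are selected and
valid; the planimetric area is accumulated over the same quads so the
ratio is internally consistent and exactly 1 on a flat surface.  The
fixed diagonal is a deterministic, oracle-checkable choice; alternative
triangulations differ at O(cell²) and the direction of any such bias is
the same for both surveys of a plot.

**Slope/aspect.**  Horn's 3×3 weighted finite differences (the stencil
behind the standard GIS slope tools).  Aspect is the downslope
direction clockwise from north; flat cells get aspect 0 by convention,
which cannot affect the ruggedness of a flat neighbourhood because
their normal is vertical.

**Vector ruggedness (VRM).**  Per cell, the unit surface normal is
(sin s · sin a, sin s · cos a, cos s); over an n-cell window the
resultant magnitude |R| gives ruggedness 1 − |R|/n ∈ [0, 1].  The
window is 3×3 by default and must contain n valid normals, else the
cell is masked.  VRM is 0 on any plane (all normals parallel) and
invariant under height offsets and 90° grid rotations; both are tested.

**Curvature.**  The ESRI general-curvature stencil: with focal Z5,
west/east Z4/Z6, north/south Z2/Z8 and cell size L,
D = ((Z4+Z6)/2 − Z5)/L², E = ((Z2+Z8)/2 − Z5)/L², curvature
= −2(D+E)·100, in units of 1/(100 z-units).  Under this formula an
upward-convex bump has negative curvature at its crest; sign
conventions differ between tools, but the plot statistic is the mean of
absolute values, which all conventions agree on.  Curvature is linear
in heights (tested cell-wise), so any constant-factor convention change
rescales, never reorders, plots.

## Registration and 2.5D volume change

Repeat surveys of one plot sit in different coordinate frames and — 
because photogrammetric scale is set by control points — at slightly
different scales, so the alignment model is a 7-parameter similarity
(scale s, rotation R, translation t).

**Closed-form similarity.**  The least-squares estimate from matched
point pairs (the plot's permanent corner pins) follows Umeyama's SVD
construction; it is exact to machine precision on noise-free pairs of
≥ 3 non-collinear points, and degenerate configurations raise rather
than returning garbage.

**Scale-adjusted ICP.**  Fine registration alternates
nearest-neighbour correspondence (k-d tree) with the closed-form
similarity fit on those correspondences, recomputing the full transform
each iteration (no incremental composition).  Residuals are
point-to-point.  Convergence: stop when the RMS nearest-neighbour
distance improves by < 1e−6 m, capped at 200 iterations.  The cap is
deliberately generous: closing a few degrees of rotation from an
identity initialisation takes point-to-point ICP on the order of a
hundred iterations, and a tight cap silently returns a transform with
~1% scale error.  The RMS history is monotone non-increasing by
construction (each fit is the exact minimiser for its correspondence
set, and re-matching can only shorten nearest-neighbour distances).

**Correspondence trimming and changed surfaces.**  By default no
correspondences are rejected.  That is the right choice for surfaces
that did not change, but on a genuinely eroded plot untrimmed ICP drags
the transform toward the reference and absorbs a large fraction of the
change signal into the registration — on our synthetic pairs roughly a
third of the eroded volume disappears this way.  The
`trim_fraction` option (reject that fraction of the worst
correspondences before each fit) restores unbiased recovery; the
end-to-end pipeline and the `volume` command's recommended usage set it
to 0.2.  Note that trimming forfeits the formal monotonicity guarantee
of the RMS history, which holds exactly only at `trim_fraction = 0`.

**2.5D differencing.**  Both registered clouds are projected onto a
common horizontal grid (the reference survey's frame is assumed
gravity-aligned); each cell's height is the mean z of its points
(median available).  Cells empty in either raster are excluded from
the comparison and counted — never interpolated.  Net volume is
Σ Δh · cell², with gain and loss accumulated separately; the default
cell matches the 1 cm DEM resolution.  Because excluded cells carry no
signal, point density must cover the grid: the synthetic sampler is
stratified, and at the default 40 000 points/m² its 5 mm strata nest
exactly inside 1 cm cells, guaranteeing full coverage.  Densities whose
stratum spacing does not divide the cell size can leave a few percent
of cells empty and bias small volume signals low — measured and
documented, hence the aligned default.

## Mixed models and multi-model inference

For each complexity response y (one value per plot × survey period):

y = Xβ + Zb + ε,  b_site ~ N(0, σ²_site),
ε_i ~ N(0, σ²_resid · δ²_{g(i)}),

with treatment coding (references: period 'before', disturbance 'low'),
a random site intercept, and δ_after a free variance-ratio multiplier
when the heteroscedastic ("varIdent") structure is on — residual spread
on reefs drops after mass mortality, and forcing equal variances
distorts the likelihood.  Continuous density predictors are rescaled to
mean 0, SD 0.5 so their coefficients are comparable with the binary
heat contrast.

**Estimation.**  Full maximum likelihood, not REML: AICc comparisons
span models with different fixed effects, and REML likelihoods are not
comparable across those.  β and the residual scale are profiled out
analytically, leaving a 1–2 dimensional optimisation over
log(σ_site/σ_resid) and log δ_after, run from three starts (one
moment-based, two jittered from a fixed stream) to guard against local
optima.  The implementation reproduces `nlme::lme(method="ML",
weights=varIdent(~1|period))` log-likelihoods and coefficients to ~1e−6
on frozen test data, and statsmodels MixedLM in the homoscedastic case.

**Standard errors and intervals.**  Coefficient covariance uses the
df-corrected residual scale RSS/(n−p) rather than the ML plug-in RSS/n,
which is biased low by (n−p)/n — material with ~10 parameters on ~50
observations.  Fit-level 95% intervals use t quantiles with containment
degrees of freedom in the style of nlme: covariates constant within a
site (disturbance contrasts) get between-site df, covariates varying
within a site (heat, densities, interactions) get within-site df.  With
a handful of sites a 1.96 normal quantile is anticonservative for
site-level contrasts; the containment construction brings simulated
coverage of nominal 95% intervals to ≈ 94% under the default study
design (9 sites × 3 plots × 2 periods, one plot missing).  The
model-averaged intervals use the conventional 1.96 multiplier, since
averaged estimates mix models with different df structures.

**Selection and averaging.**  The candidate set is all 2⁵ = 32 subsets
of {heat, disturbance, branching, plating, massive} plus the 8
interaction variants of subsets containing both heat and disturbance —
40 models, fixed lexicographic order.  AICc = −2ℓ + 2k +
2k(k+1)/(n−k−1), with k = #fixed effects + 2 variance parameters (+1
when varIdent is active).  Akaike weights are computed over all
converged candidates; the top set is Δ ≤ 4.  Averaged coefficients use
full (zero-substitution) averaging over the top set with renormalised
weights, and unconditional SEs SE̅ = Σ w′ᵢ √(seᵢ² + (βᵢ − β̅)²).
RVI is the sum of renormalised top-set weights of the models containing
each predictor (interaction tracked separately); a flag switches the
denominator to the full candidate set, since both conventions exist in
the literature.  Non-converged fits are dropped with a warning, not
fatal.  Conditional R² follows Nakagawa–Schielzeth with the
observation-weighted mean of per-period residual variances in the
denominator.

## Synthetic surveys: what they do and do not emulate

The generator's default plot-record design is 9 sites in three
disturbance strata × 3 plots × 2 survey periods with one plot dropped
(26 plots, 52 records); default coefficients describe a rugosity-like
response (strong negative heat effect, baseline declining with
disturbance, positive branching/massive effects, residual SD shrinking
after the event, δ_after = 0.6).  Growth-form densities are gamma
distributed with disturbance-dependent means, so the statistical stage
sees a realistic signal direction.

Surfaces are sums of a tilted plane, a sinusoid, and spherical-cap
bumps placed by dart-throwing with a margin of (cap radius + 5 cm) from
the plot boundary — a misaligned repeat survey does not cover an edge
band, so structure there would be invisible to the 2.5D comparison by
construction.  Caps are added (and removed) additively, so every
removal changes volume by exactly −πh²(3R−h)/3 regardless of the base
surface, giving the registration+differencing pipeline a closed-form
oracle without numerical integration.  Every generator takes an
explicit seed and is bit-reproducible; no global random state.

What passing these tests does **not** show about real data: synthetic
surfaces have no overhangs (neither do DEMs — the 2.5D representation
itself underestimates the complexity of plating/tabulate corals), their
curvature magnitudes are far larger than real reef values because cap
rims are sharp at 1 cm resolution, point clouds have uniform density
and purely vertical Gaussian noise rather than view-dependent
photogrammetric error, and erosion is instantaneous bump removal rather
than gradual rubble formation.  Registration results in particular
assume the pins are truly invariant between surveys.

## Problem sizes

Default test and acceptance runs use 1.5–2 m plots at 1 cm cells
(~40 000 cells), clouds of ~10⁵ points, 200 simulated datasets for the
coverage study and 100 replicates × 40 models for the RVI study —
sizes chosen so the full suite completes in a few minutes while keeping
Monte-Carlo error well below the tolerances asserted.
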