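# Methods

This note documents the models, numerical choices and design decisions
behind `mrtfrac`, and what the synthetic testbed does and does not show
about real assay data.

## Dose-field model

A microbeam field is an idealized periodic stripe pattern characterized
by four numbers: slit width (default 30 µm), center-to-center pitch
(default 300 µm), PVDR (default 45.77) and field size (default 20 mm
square).  The lateral profile is rectangular — dose `p` inside a stripe
of the slit width, `p/PVDR` in the valley — with an optional linear
penumbra ramp of configurable width (default 0).  The pitch of the
physical collimator is not part of its published characterization; 300
µm is the midpoint of the 200–400 µm range typical of multi-slit
collimators and is configurable.

A stripe pattern at angle θ is evaluated analytically at rotated
coordinates `s = (x−cx)cosθ + (y−cy)sinθ` about the domain center — never
by image rotation — so rotation introduces no resampling error and maps
are bit-reproducible.  A peak is centered on the rotation center at
every angle; "overlapping" fractions therefore share phase exactly.
Angles act modulo 180° (a planar stripe pattern is symmetric under
half-turns).  Whether the dish or the gantry physically rotates is
equivalent in-plane and modeled as pattern rotation.

Dose rate and intra-fraction protraction are ignored; peak/valley dose
*rates* appear only in the bookkeeping helper `valley_from_peak`
(4.31 Gy/min ÷ 45.77 ≈ 0.094 ≈ 0.09 Gy/min).

`pvdr_of_map` estimates PVDR as the mean over the central 50% of peak
stripes divided by the mean over the central 50% of valley stripes,
classified from geometry and stripe angle; a zero valley is reported as
infinite rather than an error.

## Survival integral and EUD

Per-fraction LQ kill with full inter-fraction repair at the 24 h
spacing:

    SF = (1/|A|) ∫_A exp(−Σ_i [α D_i + β D_i²]) dA .

The area normalization 1/|A| makes SF a fraction; cells are assumed not
to migrate between fractions and to respond independently.  No
incomplete-repair (Lea–Catcheside) factor, no repopulation, hypoxia or
alternative cell-kill models.

**Quadrature.**  The integrand is discontinuous at stripe edges, so
plain cell-center sampling converges only linearly for stripes oblique
to the grid.  The integral is therefore evaluated with a composite
midpoint rule, subdividing each grid cell 3×3 (`QUADRATURE_SUBSAMPLES`).
At the default 5 µm grid this keeps the relative change under grid
halving below ~3·10⁻⁵ for 4-angle plans (the stability tests require
< 10⁻⁴).  Axis-aligned patterns at the default grid are resolved
exactly (an integer number of sub-points per stripe).  For
all-microbeam plans with equal per-fraction peak dose, the two fields
`Σ u_k` and `Σ u_k²` of unit stripe patterns are cached, making dose
sweeps and inverse planning cheap; larger problems fall back to a
chunked streaming evaluation with bounded memory.

**Integration domain.**  A square or disc patch centered in the field
(grid = cell centers, center at the origin).  The general default is a
10 mm square at 5 µm; the *study design* uses a 3 mm patch (ten stripe
periods), over which the periodic survival integral has converged, to
keep simulation affordable.  A guard enforces ≥ 6 samples per slit and
that the domain lies inside the field footprint.

**EUD inversion.**  `β·E² + α·E = −ln SF` solved as
`E = 2L/(α + √(α² + 4βL))`, stable as β → 0 (the fibroblast line has
β = 4·10⁻⁵ Gy⁻², where the textbook root formula cancels
catastrophically) and continuous to the linear limit `L/α`.  Root-finding
tolerances: 10⁻⁸ in survival, 10⁻⁶ Gy in dose.

**Inverse planning.**  The per-fraction peak dose reaching a target
survival is found by bracketing + Brent root finding on the strictly
decreasing map dose → survival.  Broad-beam arms invert in closed form.

**Ordering of the arms.**  At equal per-fraction peak dose the rotated
(0/45/90/135°) schedule always yields lower survival — hence higher
single-fraction EUD — than the overlapping schedule: overlapping
fractions maximize the heterogeneity of the accumulated effect, and
averaging `exp(−·)` rewards heterogeneity.  The acceptance suite checks
this strictly across a 1–20 Gy sweep.

**Jensen property, corrected.**  Survival of a heterogeneous field
exceeds that of its mean field wherever the per-fraction survival curve
is convex, i.e. `(α + 2βD)² ≥ 2β`, guaranteed for `α ≥ √(2β)`.  This
covers every realistic radiosensitivity (both study lines included),
but it is *not* universal: for `α ≪ √(2β)` the shoulder is concave and
the inequality can reverse.  The tests assert the property on its
domain of validity and demonstrate the sharp counterexample.

## Colony-formation-assay reduction

Plating efficiency PE = 100 · colonies/seeded.  The printed form of the
survival-fraction definition is dimensionally ambiguous; the standard
normalization is implemented: SF = colonies / (seeded · PE/100), with PE
taken from the unirradiated control of the *same biological replicate*
(controls are sham-handled through the fractionation schedule).  Since
all arms share one schedule, one control set per biological replicate
serves every arm; the reduction first looks for an arm-specific control
and falls back to the replicate's pooled controls, so both layouts work.
Colony counting (the ≥ 50-cell rule) happens upstream and is metadata
here.

**LQ fitting.**  Unweighted least squares of `−ln SF = αD + βD²`
(no intercept; optional 1/SEM²-style weights).  Technical replicates
are pooled (summed counts) within each biological replicate before
fitting — three points per dose — which keeps `ln SF` defined when an
individual low-survival well counts zero colonies.  Nonnegativity is
enforced by projection: a negative estimate is clamped to zero and the
other parameter refitted; the reported covariance is that of the
unconstrained fit.  The projection leaves a small (<2%) conditional bias
in α when the true β is 0 — quantified in the test suite.

## Synthetic study generator

The generator emulates the study design: two lung lines — tumor
(α = 0.29075 Gy⁻¹, β = 0.01928 Gy⁻²; PE 0.70) and normal fibroblast
(α = 0.56606 Gy⁻¹, β = 4·10⁻⁵ Gy⁻²; PE 0.35) — under three arms
(4-fraction broad beam, overlapping microbeam, 45°-rotated microbeam) at
24 h spacing, with 3 biological × 6 technical replicates and dose levels
1, 2, 4, 6, 8 Gy.

- **Dose meaning.**  By default (`matched_eud`) the levels are target
  single-fraction EUDs, and per-fraction doses are solved per line and
  arm so that all arms share one survival at each level — mirroring the
  study's equal-survival fraction sizing.  `peak` mode interprets levels
  as physical per-fraction doses.
- **Noise.**  Colony counts are Poisson with mean
  `seeded · PE · SF_plan` (overdispersion can be layered on via the
  biological-replicate multiplier; a noiseless mode emits expectations
  for exact-recovery tests).  Treated wells seed a dose-dependent ladder
  (geometric, 100 → 2000 cells) so expected colony counts stay
  countable; controls seed 250 cells per well, sized so the pooled
  control PE is precise — an imprecise shared control correlates every
  SF of a replicate and degrades the calibration of downstream fits.
- **Biology beyond LQ.**  Multiplicative per-arm survival effects can be
  injected (e.g. a 1.5× sparing of the normal line's microbeam arms,
  standing in for intercellular-communication rescue).  Defaults are
  all-1: under the pure LQ truth the matched arms form a true null.
- **Determinism.**  One child random stream per well, split from the
  master seed in a documented canonical order; identical seeds give
  byte-identical CSVs.

What passing tests on this generator show — and what they do not: they
validate the estimation and comparison machinery (unbiasedness,
coverage, calibration, power at dominating effects) under Poisson
counting noise and the declared design.  They cannot validate the LQ
model itself, bystander/migration biology, plating-density effects or
counting errors in real assays.

## ANCOVA comparison

For each arm pair, `ln SF ~ EUD + arm` on replicate-level wells (common
slope); the group-term p-value is reported (identical to the 1-df
partial F).  An interaction model's slope-difference p is kept as a
secondary diagnostic.  ln SF is used as the variance-stabilizing
response; EUD as the covariate puts all arms on one dose axis.  Raw
pairwise p-values are reported (three pairwise tests per line, as such
tables are usually shown); Holm adjustment is available but off by
default.  An optional EUD window restricts observations before testing
(the curves of interest cross, so significance can be range-dependent).

Calibration: with a near-linear truth (β ≈ 0) the test holds its 5%
level (validated over 500 simulated null studies).  With strong
curvature (the tumor line's β) the linear-in-EUD model is *conservative*
— lack-of-fit inflates residual variance — never anti-conservative.
Mixed-effects modeling of biological replicates is out of scope.

## Pipeline

`simulate`, `plan`, `analyze` (and `all`) are pure functions of
(config, seed); every run writes a manifest with a canonical config
hash, the seed and the package version, and reruns are bit-identical.
Config is one YAML/JSON schema (versioned); artifacts are CSV; plots are
conveniences, not test surfaces.  Exit codes: 0 ok, 1 input error, 2
internal error.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each run in minutes on one CPU: 3 mm integration patches (10 stripe
periods) for study simulation, a 10 mm patch at 5 µm for dosimetric
checks, 200 repetitions for recovery coverage and 500 for calibration.
All are configuration, not constants.

## Known limitations

- Ideal rectangular stripe profiles; no transport, divergence,
  depth-dose or film-calibration modeling.
- Full inter-fraction repair assumed; no kinetics of sublethal damage.
- The finite integration patch makes matched doses depend weakly
  (~1%-level) on patch extent; the patch is part of the configuration.
- The ANCOVA is deliberately the simple common-slope linear model; with
  strongly curved survival its p-values are conservative.
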