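# Methods

This note records the scientific and numerical choices behind
`leafpart`: what the model assumes, where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Model structure and assumptions

The quantity modelled is the share of total main-stem leaf dry biomass
held by each leaf, `PC_L = Bio_L(i)/Bio_TL` (g g⁻¹, dimensionless).
Shares are modelled against normalized leaf rank `nLR = i/N ∈ (0, 1]`
rather than absolute rank, which makes plants with different final leaf
numbers comparable; the cost is that `N` (total main-stem leaf number)
must be known for every sampled plant.

Development is measured in normalized physiological time (nDPD). The
model is *descriptive*: within each of nine fine stages the share
profile is a fixed piecewise curve in `nLR`, with a single pooled
parameterization across cultivars, nitrogen levels and densities.
Treatment effects exist (they are highly significant in factorial
trials) but are absorbed into residual scatter, not parameterized. The
curves make no statement outside their declared rank intervals — those
ranks are senesced or not yet emerged — and they do not guarantee mass
conservation: summing a stage curve over a particular plant's ranks
does not give exactly 1, which is why profile predictions offer a
`renormalize` option mirroring how measured shares are computed.

### Piece domains and dispatch

Interval notation in the source tables is inconsistent (mixed and
occasionally missing brackets). The package adopts one convention:
**interior breakpoints belong to the upper piece** — pieces are
half-open `[lo, hi)` except the last piece of a stage, which is closed
above — and stage lower bounds keep their printed openness. This makes
dispatch total and unambiguous on each stage's rank union, which a grid
property test enforces at step 1e-3 including the breakpoints. Whether
the mid-seedling upper bound is open or closed is undecidable from the
source; the convention closes it at 0.50 as the stage's final piece.

### Published coefficients

The 41 coefficient estimates are stored to their three printed decimals
exactly, with no re-derived precision, including the two coefficients
whose *t*-tests are not significant (`Lbo1`, p = 0.912; `Llb1`,
p = 0.622): the shipped file reproduces the published model as printed.
One consequence is accepted deliberately: the late-seedling upper piece
is a power law with a large negative exponent (`Lls3·nLR^Lls4`,
`Lls4 = −7.998`), which produces values far above 1 near its lower
domain edge. Evaluation is finite everywhere on the declared domains
(property-tested) and per-plant renormalization keeps generated data
physical, but users refitting that stage should treat the printed form
with caution.

### Physical-range guards

Two clamps keep predictions physical near domain edges, both emitting
warnings so they cannot act silently:

* the rank-trend curve `Llr1·ln(nDPD) + Llr2` is negative for
  nDPD ≲ 0.23; predictions are clamped into (1e-6, 1];
* the late-blooming parabola dips below zero for nLR ≳ 0.99;
  negative share predictions are clipped to 0 and flagged. In the
  trial generator a clipped (zero-share) rank is treated as a senesced
  leaf and not emitted, so every generated dry weight is positive.

## Stage classification

Only the coarse window boundaries (0.428, 0.640) are data-derived. The
nine fine stages have no published numeric cutoffs, so they are
configuration: by default each coarse window is split evenly among its
sub-stages, and the onset of maturity (silique dominance) is a separate
knob defaulting to nDPD = 0.90. Callers who know the fine stage can
pass it directly and bypass classification entirely; classification
edges are half-open with the cutoff belonging to the later stage.

## Phenology accumulator

The daily increment is `k_j · T_ebj^p_j · T_euj^q_j · P_ej^G_j ·
f(E_Ci)` with all effect factors contractually in [0, 1]. The printed
form of the increment is typographically ambiguous about a leading
exponential; both readings are implemented (`leading="k"`, the default,
or `"exp_k"`). The temperature/photoperiod/vernalization response
shapes belong to a full rapeseed phenology model and are out of scope
here: the default effect functions return 1 (the agronomic factor
passes through its per-day input), so the module degrades to calendar
accumulation at rate `k_j` until response curves are plugged in.

## Fitting

* Linear, quadratic and logarithmic pieces are ordinary least squares
  (via statsmodels); coefficient order is highest-degree-first with the
  intercept last, matching the parameter tables.
* The power law `a·x^b` is fitted by nonlinear least squares on the
  original scale, initialized from a log–log OLS fit on the positive
  responses. Original-scale fitting is chosen because the tabulated
  *r* refers to untransformed shares; pure log–log estimates are
  available by calling the initialization yourself.
* Significance: two-sided *t* with `n − p` degrees of freedom per
  coefficient, *F* for the overall regression. For the nonlinear fit
  both derive from the curvature approximation of the covariance.
* The reported *r* is the Pearson correlation of fitted versus observed
  values. For multiple regression this is not identical to a
  signed bivariate *r*; the choice is the one that is well defined for
  every form.
* Form selection ranks candidates by |r| (rounded at 1e-9), then lower
  residual SD, then fewer coefficients, so exact ties resolve to the
  more parsimonious form.
* Fits pool all treatments, matching the single published
  parameterization per stage.

## Synthetic trials: what they are and are not

The generator emulates the *structure* of a destructive-sampling
factorial trial: a cultivar × nitrogen × density layout (default
2 × 3 × 3), four plants per treatment per date (within the realistic
three-to-five range), and nine sampling dates placed so each fine stage
is visited once. Green leaf number follows a unimodal integer
trajectory peaking (exactly at the plant's maximum, default 22 leaves)
at nDPD = 0.64 and declining to a ~20 % residual at maturity; the
concave rise (shape exponent 0.8) reflects rapid pre-winter leaf
production. Leaf counts get Poisson jitter (clipped to ≥ 1), and dry
weights get multiplicative lognormal noise, `exp(N(0, σ))` with
σ = 0.10 by default — a 10 % coefficient of variation typical of
destructive dry-weight measurements. The lognormal choice preserves
positivity and the per-plant sum-to-one property of measured shares.
No published dispersion statistics exist for the per-rank scatter, so
σ is exposed as configuration. Every stochastic step flows from one
integer seed (default 20120101); identical designs and seeds give
byte-identical tables.

What the generator does **not** emulate: treatment effects on the
curves (all cells share one truth), weather and soil dynamics,
within-plant measurement correlation, and missing-data patterns of real
trials. Passing tests therefore demonstrate the correctness of the
estimation and validation machinery under the model's own assumptions,
not the model's adequacy for new field data.

### Renormalization and round trips

Measured shares are computed per plant (each plant's shares sum to 1),
but the stage curves do not integrate to exactly 1 over an arbitrary
plant's ranks. Consequently refitting *renormalized* shares recovers
the curve shapes up to a plant-level scale factor — the same situation
a real analysis faces. The exact round-trip checks therefore take the
route where the truth is identifiable: (i) the Monte-Carlo recovery
harness samples each curve directly (noiseless recovery is exact to
< 1e-8 for every piece, and noisy recovery is unbiased to within
Monte-Carlo error); and (ii) a trial-table round trip with
`renormalize=False`, where dividing the emitted weights by the known
total-biomass curve returns the raw curve values and refitting every
stage reproduces the generating coefficients to 1e-6.

## Validation statistics

`RMSE`, `d_a` (observed minus simulated, signed), `d_ap`
(|d_a| as a percentage of the mean observation) and Pearson *r*. The
`n* = n − 1` small-sample note in the source is attached ambiguously;
it is applied to the RMSE denominator only, for n ≥ 30, with a flag
(`bessel_rmse=False`, `--plain-n-rmse`) restoring the plain-n reading.
The `nLR` group's statistics are reported as dimensionless (normalized
rank is a ratio) even where source tables label them g g⁻¹. In grouped
validation the rank-trend group compares each discrete leaf rank to a
smooth trend curve, so its RMSE is positive even for self-consistent
data — only the stage-share groups vanish under a noiseless round trip.

## Problem sizes

The shipped Monte-Carlo demonstrations use 100 replicates at the
source sample sizes (n = 1167 for the rank trend, n = 78 for the
mature stage) and a 10-replicate, 300-point sweep over all stage
pieces; the full test suite and the acceptance script each run in well
under a minute on one CPU.

## Known limitations

* Fine-stage nDPD cutoffs are a modelling convention, not data.
* The power-law piece of the late seedling stage is reproduced as
  printed despite its implausible magnitudes near the domain edge (see
  above).
* No per-treatment or mixed-effects fitting; pooled fixed curves only.
* Branch and pod partitioning, and mechanistic source–sink transport,
  are out of scope: main-stem leaves only.
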