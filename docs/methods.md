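# Methods

## Model

Activity centers are a homogeneous Poisson process with intensity `D`
(reported per 100 km²) over a discretised state space: the habitat mask,
a regular grid of points each owning `cell_area` km².  Conditional on a
center `s`, detections are independent Bernoulli trials per detector ×
occasion (a *proximity* detector: it records an identity without holding
the animal, so several animals can be recorded at one detector and one
animal at several detectors within an occasion) with half-normal
probability `p = g0·exp(−d²/2σ²)`.  The 10-day field sessions the data
model emulates are single occasions.

The fitted likelihood is the full (Poisson-N) integrated likelihood; the
number of detected animals `n` is itself random, which is what lets the
model report `E(N) = D̂ × area` directly.  The `ln n!` term is constant
in the parameters but retained so log-likelihood values are comparable
across software.  The undetected-animal component (through
`Λ = D·A·Σ_m ψ_c·p·_c(s_m)`) always uses *naive* pre-response detection
probabilities: an animal that was never caught can never have developed a
learned response.

### Detection covariates

`g0` is logit-linear in: an occasion factor `t` (intercept + K−1
contrasts), at most one behavioural response, and sex.  The behavioural
state `z_ijk` is: `b` — detected anywhere before occasion `k`; `bk` —
detected at detector `j` before `k`; `Bk` — detected at `j` on occasion
`k−1` exactly.  Behavioural responses act on `g0` only; `σ` is log-linear
with an optional sex effect.  Sex enters as a two-level known individual
class with an estimated mixture proportion `ψ` (logit link) weighting the
undetected component; animals of unknown sex are marginalised over the
two classes.  A consequence of estimating `ψ` is that this package's
parameter count for sex models is one larger than conventions that treat
the sex split as fixed.

The model family driver fits 12 a-priori structures: `g0` ∈ {·, t, b, bk,
Bk, sex} crossed with `σ` ∈ {·, sex}; time and behaviour are never
combined.  AICc uses the number of distinct individuals as the effective
sample size — the convention under which published SCR ranking tables
reproduce exactly — and models within 2 AICc units are flagged as
competing.

## Likelihood evaluation and fitting

The per-animal history probability over the mask factors into (i) a naive
survival term shared by all animals of a sex class, (ii) rank-one and
sparse per-animal corrections for occasions spent in a non-naive
behavioural state, and (iii) a detection term that is linear in the
count-weighted squared distances.  One evaluation therefore costs a few
dense passes over the (mask × detector) kernel plus sparse products —
no (animal × mask × detector × occasion) tensor is ever materialised.
An optional cutoff radius (used by the simulation engine at 6σ) drops
mask–detector pairs whose survival contribution is below `exp(−18)`;
detection terms remain exact because they bypass the kernel entirely.
The truncation is only valid while `σ ≲ cutoff/5`, so any evaluation at a
larger σ (e.g. an optimizer excursion) automatically falls back to the
exact dense path — without this guard a runaway σ can masquerade as a
likelihood gain.

Optimisation is quasi-Newton (L-BFGS-B) on the link scale
(`log D, logit g0, …, log σ, logit ψ`), with an analytic gradient for the
null model (validated against finite differences in the test suite) and
finite differences otherwise; a Nelder–Mead polish runs when the
quasi-Newton search reports failure.  Default starts are data moments:
`g0` from detections per animal-occasion, `σ` from half the mean distance
between an animal's recapture locations (trap-spacing fallback), `D` from
`n / mask area`, `ψ = 0.5`.  The covariance is the inverse observed
information, differenced centrally from the analytic gradient (null
model) or the function values (step `1e-3·max(|θ|, 0.1)`); a singular
information matrix leaves SEs absent with a warning rather than failing
the fit.

Wald intervals on the link scale are back-transformed for `g0`, `σ` and
`ψ`; density and `E(N)` use the lognormal interval
`[D̂/C, D̂·C]`, `C = exp(1.96·√(ln(1+(SE/D̂)²)))`, which matches the
asymmetric intervals conventionally printed for density.  The
`check_buffer` diagnostic refits on masks with the buffer rescaled and
flags relative density changes above 1% (default), indicating an
inadequate state space.

### Mask geometry

`build_mask` places an `nx × ny` lattice inclusive of the trap bounding
box expanded by the buffer on all sides; `ny` is derived from `nx` to
keep cells square, and by default points farther than the buffer from
every detector are clipped out, matching the "radius around the
detectors" convention for state spaces.  Grid refinement matters: with
cell spacing near `σ` the Riemann sum over activity centers biases `D̂`
low by ~10% (measured on this package's own simulations); a spacing of
**≤ 0.4σ** keeps that numerical bias below the Monte-Carlo noise of a
100-replicate study, and `mask_resolution()` encodes that rule.  The
scenario runner's default of `nx = 64` reflects common practice and is
adequate for `σ ≥ 10` km at these extents; the acceptance script passes
finer grids for `σ = 5` km.

## Synthetic data

The layout generators reproduce the *statistical structure* of the two
survey designs, whose field coordinates are not published:

- **Intensive**: five 9×9 snare arrays on a √2.6 km ≈ 1.61 km grid (2.6
  km² cells, ≈210 km² per array), labelled A–E west to east.  Default
  origins space the arrays ~45 km apart along an east–west band, the
  design's documented scale; origins are configurable, and an optional
  per-array dropout (e.g. two snares from B) reproduces the fielded count
  of 403.  Optional jitter places each snare uniformly within its cell.
- **Extensive**: sighting counts per 10×10 km cell are Poisson draws from
  a clustered Gaussian-mixture intensity surface (three clusters over a
  120×120 km region by default, emulating the concentrated sightings of
  a recolonising population; expected total ≈450 sightings so that the
  allocation rule lands near its target before rescaling).  Cells with
  1–3 sightings get one snare, 4–5 four, 6–7 five, ≥8 six, zero-sighting
  cells none; largest-remainder rounding rescales the total to exactly
  378.  Placement is uniform within cells under a best-effort global 3 km
  minimum spacing (rejection sampling; relaxations are logged).

Populations are homogeneous Poisson over the mask (`N ~ Poisson(D·A/100)`
— the same assumption the likelihood makes; a fixed-N mode exists for
variance experiments), with uniform placement within a uniformly chosen
cell and Bernoulli(0.5) sexes by default (configurable; field sex ratios
differ).  Encounter histories are Bernoulli per animal × detector ×
occasion from the half-normal, with an optional behavioural shift of
logit(g0) driven by the running prior-detection state.  Never-detected
animals are dropped with the count reported.

What the generators do *not* emulate: habitat-driven snare placement
(forest cover, land access), inhomogeneous animal density, sex-specific
movement, temporary emigration, or lab-side identification error
(genotyping dropout, misidentification).  Passing simulation checks
therefore demonstrates correctness of the estimator under the model's own
assumptions and the designs' geometry — not robustness to those field
realities.

## Simulation study

A scenario = (configuration, D, g0, σ): the configuration's layout is
generated once per study seed; the mask buffer follows the radius rule
(30 km for σ ≤ 10, 45 km for σ = 15); each replicate simulates a
population and histories, fits the null model `g0(.), σ(.)` (the study
estimates the basic parameters; behavioural models are not simulated in
the grid), and records `D̂`, its SE and lognormal CI.  Accuracy is
`%RB = 100·(mean D̂ − D)/D` and `%COV` = percent of CIs containing `D`
(closed endpoints).  Replicates that fail to converge, lack a usable SE,
or detect fewer than 3 individuals are excluded and counted; both the SD
of replicate estimates and the mean per-replicate model SE are reported,
since tabulated "SE" columns are ambiguous between the two.  Per-replicate
random streams derive from `(study seed, replicate index)`, so any
replicate reruns in isolation.  Warm-starting each fit at the previous
replicate's MLE roughly halves optimisation cost without affecting the
optimum.

Problem sizes: the acceptance script runs 100 replicates per low-density
scenario (250 for the intensive σ = 5 cells, whose small detected samples
make their per-replicate variance highest — extra replicates there
balance the Monte-Carlo precision of the per-scenario %RB estimates) and
60 for the high-density reference scenario, with masks at `nx = 64`
(intensive σ = 10, the reference grid) or the 0.4σ spacing rule
elsewhere; the test suite runs
a 40-replicate version of the same suite and widens its thresholds by
three Monte-Carlo standard errors computed from the observed replicate
spread.  At these sizes the Monte-Carlo standard error of a scenario's
%RB is roughly 1–3 percentage points, which bounds how sharply a single
run can be compared against tabulated values.

## Known limitations

- Homogeneous density only; no habitat covariates on `D`.
- Half-normal detection only (no hazard-rate or exponential forms).
- Single-session likelihood; multi-year data must be fitted per session.
- Wald/lognormal intervals only (no profile likelihood or bootstrap).
- The sex mixture assumes exactly two classes and known class for sexed
  animals; misclassification is not modelled.
- The analytic gradient covers the null model; richer models use finite
  differences and fit noticeably slower on large masks.
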