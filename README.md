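# scrdens

Maximum-likelihood **spatial capture–recapture (SCR)** density estimation
for detector-array surveys (e.g. DNA hair snares), with model selection
over detection covariates and a simulation engine for evaluating how trap
configuration affects the accuracy and precision of density estimates.

## Who this is for

Wildlife biologists and quantitative ecologists estimating the density of
wide-ranging, low-density animals (bears and other large carnivores are
the motivating case) from non-invasive detector arrays, and anyone
designing such a survey who wants to quantify, before fieldwork, the bias
and confidence-interval coverage a candidate trap layout would deliver.

## The model

Each animal has a latent activity center `s` distributed as a homogeneous
Poisson process with density `D` over a discretised state space (the
*habitat mask*, by default a 3σ-scale buffer around the detectors).
Detection at detector `j` on occasion `k` is Bernoulli with the
half-normal function

    p_jk(s) = g0 · exp( −d(s, x_j)² / (2σ²) )

where `g0` is the detection probability at the activity center and `σ`
(km) sets how fast detection decays with distance.  Integrating the
activity centers over the mask (cell area `A`) gives the full Poisson-N
likelihood for the `n` detected individuals

    lnL = −Λ + n·ln D + Σᵢ ln( ψ_cᵢ · A · Σ_m Pr(ωᵢ | s_m) ) − ln n!,
    Λ   = D · A · Σ_m Σ_c ψ_c · p·_c(s_m),

with `p·(s) = 1 − Π_{j,k} (1 − p_jk(s))` the probability of being
detected at least once and `ψ` a sex-mixture proportion (dropped for
sexless models).  `g0` can additionally depend on an occasion factor
(`t`), a behavioural response to prior detection (global `b`,
detector-specific `bk`, or Markovian `Bk`) or sex; `σ` on sex.  Models
are ranked by AICc (effective sample size = number of individuals
detected) with Akaike weights; density intervals use the lognormal
convention `[D̂/C, D̂·C]`, `C = exp(1.96·√(ln(1+(SE/D̂)²)))`, and the
expected population size is `E(N) = D̂ × area`.

The package also generates the two trap layouts whose design trade-off it
studies — a spatially *extensive* layout (378 snares allocated over a
10×10 km sighting grid proportional to a clustered intensity surface)
and an *intensive* layout (five 9×9 arrays of 2.6 km² cells) — and
measures estimator accuracy as percent relative bias (%RB) and 95% CI
coverage (%COV) over replicated simulations.

## Worked example

```python
import scrdens as sd

traps = sd.gen_intensive_traps()                 # five 9x9 arrays, 405 snares
mask  = sd.build_mask(traps, buffer=30.0, nx=64) # ~17,400 km^2 state space
pop   = sd.sim_population(D=1.0, mask=mask, seed=1)
data  = sd.sim_captures(pop, traps, g0=0.1, sigma=10.0, seed=2)
fit   = sd.fit_scr(sd.ModelSpec.from_formula("g0~1, sigma~1"),
                   data, traps, mask)
print(fit)
```

prints (for these seeds)

```
g0(.), sigma(.): lnL=-6578.885, K=3, n=134, converged=True
parameter  estimate       se      lcl       ucl   cv_pct
        D  1.002639 0.090843 0.839807  1.197042 9.060440
       g0  0.098468 0.005386 0.088404  0.109540 5.469631
    sigma  9.833120 0.240324 9.373197 10.315611 2.444027
```

i.e. from 134 detected individuals the model recovers the simulation
truth (`D = 1.0` per 100 km², `g0 = 0.1`, `σ = 10` km) within one
standard error; `D`'s asymmetric CI is the lognormal interval.  See
`examples/` for model selection, detection filtering and design-accuracy
scripts, and the `scrdens` CLI (`scrdens fit`, `scrdens summarize`,
`scrdens simulate`, `scrdens grid`) for file-based use.

## Layout

- `src/scrdens/io.py` — trap/capture file formats, filtering, summaries
- `src/scrdens/spatial.py` — distances, habitat-mask construction
- `src/scrdens/detection.py` — half-normal detection, model formulas, covariates
- `src/scrdens/likelihood.py` — integrated likelihood, fitting, CIs, E(N)
- `src/scrdens/selection.py` — AICc, Akaike weights, 12-model family
- `src/scrdens/simulate.py` — layout generators, populations, encounter histories
- `src/scrdens/bias.py` — scenario runner, %RB / %COV metrics
- `docs/methods.md` — modelling and numerical details
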