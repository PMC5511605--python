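# optimet

Optimal design of multi-environment trials (METs) for calibrating crop
growth models, with wheat heading date as the working example.

## The problem

Gene-to-phenotype approaches in plant breeding couple a crop growth model
(CGM) with genomic prediction: each variety is described by a small vector
of *genetic parameters* — CGM inputs that depend on the genotype but not on
the environment — which are estimated from field phenotypes, mapped and
predicted from markers, and finally fed back through the CGM to predict
performance in new environments. The whole chain stands or falls on the
quality of the parameter estimates, and that quality is set by the choice
of the field environments (location × sowing date) used for calibration —
a choice that must be made *before* any data exist.

`optimet` implements a Bayesian preposterior criterion for that choice.
For wheat phenology the genetic parameters are

* **VAI** — response of vernalization rate to temperature (day⁻¹ °C⁻¹),
* **SLDL** — day-length response of leaf production (leaves h⁻¹),
* **Phyl** — the phyllochron (°Cd leaf⁻¹),

with expert prior ranges VAI ∈ [0, 0.01], SLDL ∈ [0, 1], Phyl ∈ [80, 120].

## The criterion

Take m a-priori parameter vectors θ₁…θ_m (by default a regular grid over
the prior box) and the noise-free model outputs f(θ_u, E_j) for every
candidate environment. For a design d of Z environments with K
replications (n_y = Z·K observations per variety), form the likelihood of
θ_u given synthetic data generated from θ_v,

    L_uv = (4πσ_e²)^(−n_y/2) · exp(−Δ_uvᵀΔ_uv / 4σ_e²),
    Δ_uv = ( f(θ_u, E_j) − f(θ_v, E_j) )_{j ∈ d},

normalize columns to a weight matrix W_uv = L_uv / Σ_u L_uv, and score

    OptiMET(d) = Σ_{u,v} dist(θ_u, θ_v) · W_uv,

where dist is the range-normalized Euclidean distance between parameter
vectors. Small values mean the design maps distant parameter vectors to
distant outputs; the best design minimizes the criterion, found here by a
greedy exchange search with restarts. Because next season's weather is
unknown, candidates are scored on the "average year" — per-calendar-day
mean temperatures over past years — while day length follows from
latitude alone.

Around the criterion the package provides the full benchmark loop: a
compact three-phase wheat phenology model, synthetic weather and
LD-structured inbred panels with geometric-series QTL architectures,
Metropolis-within-Gibbs estimation of (θ, σ_e²) under uniform/inverse-gamma
priors with posterior-mode point estimates, VanRaden kinship, G-BLUP
genomic prediction, a kinship-corrected association scan, and the
NRMSE / NRMSE* / NPSE design-quality metrics.

## Worked example

Score and optimize a trial network over 6 sites × 4 sowing dates:

```python
import datetime as dt
import numpy as np

from optimet import (
    ClimateParams, Site, build_environments, build_grid,
    generate_synthetic_weather, DEFAULT_BOUNDS,
    compute_candidate_outputs, exchange_search, OptimetCriterion,
)
from optimet.environments import average_year, extend_cyclic

# 1. candidate sites and a 6-year synthetic weather record
sites = [Site(f"s{i}", f"site {i}", lat)
         for i, lat in enumerate(np.linspace(43.0, 50.5, 6))]
weather = generate_synthetic_weather(sites, 6, ClimateParams(), seed=42,
                                     start_year=2001)
by_site = {}
for series in weather:
    by_site.setdefault(series.site_id, []).append(series)

# 2. the "average year" per site, extended so late sowings see a full season
avg = {sid: extend_cyclic(average_year(years), 730)
       for sid, years in by_site.items()}

# 3. candidate environments: every site x sowing date combination
dates = [dt.date(2001, 9, 15), dt.date(2001, 10, 15),
         dt.date(2001, 11, 15), dt.date(2002, 3, 15)]
candidates = build_environments(sites, dates, avg, horizon_days=300)
print(f"{len(candidates)} candidate environments")

# 4. score the a-priori parameter grid on every candidate, then optimize
grid = build_grid(DEFAULT_BOUNDS, 8)
outputs = compute_candidate_outputs(grid, candidates)
criterion = OptimetCriterion(grid, outputs, sigma2_e=2.0**2)
result = exchange_search(candidates, Z=4, criterion_fn=criterion,
                         n_iter=800, n_restarts=2, seed=0)
print(f"best OptiMET value: {result.value:.3f}")
for env_id in result.design.env_ids:
    print(f"  {env_id}")
```

which prints

```
24 candidate environments
best OptiMET value: 98.075
  s4:2002-03-15
  s5:2001-09-15
  s5:2001-11-15
  s5:2002-03-15
```

The selected network mixes autumn and spring sowings at contrasting
latitudes — autumn sowings spread vernalization-saturation dates across
the steep part of the day-length season (separating VAI), while the
winter/spring contrast decouples the photoperiod response (SLDL) from the
phyllochron. The criterion value itself is only meaningful relative to
other designs of the same size: lower is better.

The same operations are available from the shell (`optimet precompute`,
`optimet score`, `optimet optimize`, `optimet estimate`,
`optimet evaluate`, `optimet pipeline`); `optimet pipeline --config
run.yaml --out dir/ --seed 1` runs the full design-strategy benchmark
(weather → genotypes/QTL → designs → phenotypes → MCMC → QTL detection →
genomic prediction → heading-time validation) and writes a tidy
`report.tsv`.

See `docs/methods.md` for the model equations, parameter meanings,
numerical choices and known limitations.

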