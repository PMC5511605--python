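# Methods

This note documents the models implemented in `optimet`, the defaults and
their rationale, the numerical choices, and what the synthetic-data
benchmark does and does not demonstrate.

## 1. Observation model

Phenotypes follow

    Y_ijk = f(θ_i, E_j) + e_ijk,   e_ijk ~ N(0, σ_e²) iid,

for genotype i, environment j and replication k, where f is the crop
model below, θ_i = (VAI_i, SLDL_i, Phyl_i) the genetic parameters and E_j
the environment's daily temperature and day-length series. Residuals are
homoscedastic by default; an option attributes one σ_j² per environment
(heteroscedasticity), which matters for real multi-season data where
scoring precision differs between trials. The default residual scale,
σ_e = 2 days, is the spread typical of visual heading notes in the field.

## 2. Crop phenology model

Wheat development from sowing to heading is modelled in three phases on
daily inputs (mean temperature T_d in °C, day length DL_d in hours).
Thermal time is Σ max(0, T_d) (base 0 °C). Within the final day of each
phase, thermal time is interpolated linearly, so outputs are real-valued
days; this avoids spurious ties between nearby parameter vectors, which
would blind the design criterion.

1. **Sowing → emergence** at cumulative thermal time `tt_em` = 150 °Cd.
2. **Emergence → flag leaf.** Vernalization accumulates daily from
   emergence (the seedling, not the dry seed, senses cold) at rate

       dV = VBEE + VAI · T_eff,   T_eff = max(0, min(T, 16 − T, 8)),

   until V = 1. The triangular effectiveness — maximal at cool
   temperatures (≈ 8 °C), zero at or above 16 °C — is standard wheat
   physiology and is load-bearing here: it postpones saturation in warm
   autumns into the steep part of the day-length season, which is what
   lets field trials separate vernalization genotypes. VBEE = 0.005 day⁻¹
   bounds the wait at 200 days after emergence even for VAI = 0.
   The final leaf number is set by the day length on the day vernalization
   saturates (or the emergence day, if saturation happened first):

       FLN = l_base + SLDL · max(0, dl_sat − DL(day_v)),

   with l_base = 8 leaves and dl_sat = 15 h. Leaves appear at one per
   `Phyl` degree-days.
3. **Flag leaf → heading**: a further `n_tail` = 2 phyllochrons.

Heading therefore occurs when post-sowing thermal time reaches
`tt_em + (FLN + n_tail) · Phyl`. At constant temperature and constant day
length the model has an exact closed form (e.g. 57.5 days at 20 °C with
SLDL = 0, Phyl = 100), which the tests verify to < 0.01 day.

**Parameter identifiability.** Phyl scales the whole post-emergence
duration and is always well identified. SLDL is identified by day-length
contrast between environments (winter deficits of 5–7 h vs spring
deficits near zero). VAI acts *only* through the day length read at
saturation: its leverage is proportional to SLDL, so for genotypes with
SLDL near zero VAI is unidentifiable in principle — their posterior is
the prior. This is a structural property of the model family (at warm
constant temperature the model must reduce to the photoperiod-only
closed form, so vernalization cannot gate heading directly), and it puts
a floor of roughly 0.10–0.15 on the population NRMSE of VAI under
realistic noise. Recovery experiments should therefore judge VAI against
that floor, not against the other two parameters.

**Monotonicity.** Heading is non-decreasing in Phyl everywhere, and
non-increasing in VAI / temperature whenever the photoperiod channel is
held fixed (constant day length or SLDL = 0). In seasonal environments
the VAI ordering can genuinely invert: earlier saturation can read a
*shorter* day length (e.g. spring sowings saturating before the solstice),
raising FLN. The spring response to VAI is V-shaped as a result — a real
feature with consequences for the criterion (below).

## 3. The design criterion

With m a-priori parameter vectors θ_u (default: the Cartesian grid over
the prior box) and cached noise-free outputs f(θ_u, E_j):

    L_uv(d) = (4πσ_e²)^(−n_y/2) exp(−K Σ_{j∈d} (f(θ_u,E_j) − f(θ_v,E_j))² / 4σ_e²)
    W_uv    = L_uv / Σ_u L_uv          (columns sum to 1)
    OptiMET(d) = Σ_uv dist(θ_u, θ_v) W_uv,

dist being the bounds-normalized Euclidean distance. The likelihood
matrix is symmetric, so normalizing rows instead of columns gives the
same value (tested); the (4πσ_e²)^(−n_y/2) prefactor cancels in W. All
algebra is done in log space with per-column max subtraction: on realistic
output contrasts (tens of days at σ_e = 2) the natural-scale exponent
underflows. Limits: σ_e² → ∞ gives the mean pairwise grid distance
(design-independent); σ_e² → 0 gives 0 for any design whose output
vectors separate the grid.

σ_e inside the criterion defaults to the observation-noise scale (2
days). It only sets the contrast scale at which designs are ranked.

**Grid resolution matters.** With a coarse grid (5 levels per parameter)
the criterion cannot see near-aliased VAI pairs — the V-shaped spring
response means two distant VAI values can collide between grid points —
and occasionally selects September+March-only designs whose posteriors
are bimodal. Eight levels per parameter (m = 512) is the smallest
resolution we found reliable and is the pipeline default; ten (m = 1000)
is used for final design selection.

**Search.** The exchange algorithm proposes swapping one in-design
environment (uniform) for one out-of-design environment (uniform) and
accepts strict decreases only; ties reject. Defaults are 3000 iterations
× 4 restarts; on enumerable instances (J = 12, Z = 3) it recovers the
exhaustive optimum in ≥ 19/20 seeded runs. The exhaustive oracle is
capped at 10⁵ subsets and breaks ties toward the lexicographically first
subset by environment id.

## 4. Bayesian estimation

Priors: VAI ~ U(0, 0.01), SLDL ~ U(0, 1), Phyl ~ U(80, 120);
σ_e² ~ inverse-gamma with shape 4 and scale 0.2 (shape–scale
parameterization, density ∝ x^(−5) e^(−0.2/x), mean ≈ 0.067 days²). The
variance prior is deliberately weak but note that shape 4 acts like ~8
pseudo-observations of very small variance: with few records per variety
it pulls the posterior of σ² below the generating value, which the tests
account for.

The sampler is Metropolis-within-Gibbs: for each variety, a joint
Gaussian random walk on its three coordinates (sd = 2.5 % of each prior
range, per-variety scale adapted toward 20–40 % acceptance during
burn-in, then frozen so the retained chain is a valid Markov chain),
mixed with a 5 % chance of an independence proposal from the uniform
prior — under a flat prior its Hastings ratio is 1, and it lets chains
hop between the posterior modes that V-shaped environment responses
create. Then the variance block: a random walk on log σ² with Jacobian
correction (default), or an exact conjugate inverse-gamma Gibbs draw
(used by the conjugacy tests). Varieties are conditionally independent
given σ², so all variety proposals are evaluated in one vectorized crop
model call per environment; 20,000 sweeps for 20 varieties on 4
environments take well under a minute. Defaults: 20,000 iterations, 1000
burn-in, 19,000 retained.

**Point estimates** are posterior modes: a binned Gaussian-kernel density
on a 512-point grid spanning the prior support, with (i) reflection of
mass at the support edges so boundary modes are not biased inward,
(ii) Silverman's constant at the n^(−1/7) mode-estimation rate on the
autocorrelation-corrected effective sample size (plain Silverman on the
nominal chain length undersmooths MCMC output badly), and (iii) a final
polish that averages the draws within one bandwidth of the density
argmax. On 50k Gaussian draws the mode lands within 0.04 sd of the
center; an 80/20 mixture returns the heavy mode; boundary-piled samples
return the boundary.

## 5. Synthetic data

**Weather.** Daily mean temperature per site is a seasonal sinusoid —
annual mean 13.5 − 0.25·(latitude − 45) °C, amplitude 8 °C, coldest day
20 — plus AR(1) noise (stationary sd 2.5 °C, lag-1 correlation 0.7,
continuous across year boundaries). These are plausible temperate values;
only the contrast between environments matters for design ranking. The
"average year" drops Feb 29 and averages by calendar day; for scoring it
is extended periodically so late sowings see a full season.

**Genotypes.** Inbred haplotypes are mosaics of ancestral segments along
a genetic map: each marker copies the previous marker's segment with
probability 1 − 2r (r the Haldane recombination fraction of the interval)
and otherwise starts a fresh segment drawn at the marker's ancestral
frequency (uniform in the configured MAF range, orientation randomized).
Markers at zero distance are in complete LD and squared correlation
decays as e^(−4d) with distance d in Morgans. The benchmark genome — 7
chromosomes × 150 markers × 150 cM — is a desk-scale stand-in for a
high-density array; it reproduces distance-decaying LD and a realistic
MAF spectrum but not real linkage maps, population structure, or
ascertainment bias.

**Trait architecture.** Per parameter, 25 markers become QTL with
|effects| following a geometric series (ratio 0.9, random signs); line
scores are affinely rescaled to span the middle 90 % of the prior range,
and all 75 QTL columns are removed from the analysis matrix. Many small
effects mean single-QTL detection power is intrinsically low — a feature,
since it matches the polygenic regime genomic selection is designed for.

## 6. Benchmark pipeline and metrics

One run: generate weather and a panel; split calibration/validation
(once); select designs on the average year — criterion-optimal, random
with 0–Z winter sowings, a reasoned sample covering all sowing periods,
and a fixed three-site expert network (latitude gradient, three November
sowings plus a southern March sowing); then per evaluation season and
design, simulate phenotypes, re-estimate parameters by MCMC, and score:

* **NRMSE** per parameter against simulated truth, normalized by the
  prior ranges;
* **NRMSE\*** and **NPSE** against full-data reference estimates,
  normalized by the observed range of the references (NPSE averages the
  squared error over all retained draws, so it adds posterior spread to
  the bias of the point estimate);
* **QTL detection power**: fraction of simulated QTL with a marker
  strictly within 1 cM reaching p < 0.05/25 in the mixed-model scan
  (polygenic background with VanRaden kinship, variance components
  estimated once under the null and reused per marker);
* **genomic prediction accuracy**: Pearson correlation between G-BLUP
  predictions and true parameter values of the validation lines (REML by
  bounded 1-D search on log λ over the spectral decomposition of the
  training kinship block);
* **heading-time accuracy/RMSE**: predicted parameters (clipped to the
  prior box) fed back through the crop model in held-out validation
  environments, compared with the noise-free model output at the true
  parameters, pooled over lines × environments.

Desk-scale defaults (40–60 calibration lines, ~1000 markers, 1500–2500
MCMC sweeps, grid 8, exchange 600×2) keep a full replicate under ~20 s;
at that scale the criterion-selected design beats the mean of ten random
designs on across-parameter mean NRMSE in 10/10 seeded replicates
(typically 0.10–0.13 vs 0.18–0.22) and roughly doubles mean detection
power. Survey-scale sizes (39 sites, 156 candidates, 100 lines, 20k
markers, 20,000 sweeps) are reachable purely through the YAML config.

## 7. Known limitations

* The phenology model is a compact three-phase variant: no cultivar-
  specific emergence, no leaf-number floor from pre-saturation leaf
  emission, no anthesis/heading distinction, no yield or resource
  dynamics. It reproduces the qualitative roles of VAI/SLDL/Phyl, not any
  calibrated cultivar.
* VAI identifiability is bounded by the SLDL-proportional day-length
  channel (section 2); population NRMSE for VAI sits near 0.10–0.15 even
  for criterion-optimal designs at 2-day noise.
* The criterion assumes the residual scale σ_e and evaluates noise-free
  confusability on the average year; it does not model inter-annual
  variance, posterior multimodality, or the mode estimator's behavior,
  which is precisely why the benchmark loop exists.
* Synthetic weather has no radiation/rainfall covariates and the genotype
  generator has no population structure; conclusions about real panels
  with structure (where the scan's "no structure effect" choice would be
  anticonservative) do not follow.
* Heritability is not estimated anywhere; design comparisons are made at
  a fixed, known noise scale.
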