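# smlmq

Quantitative single-molecule localization microscopy (PALM/STORM) for
plasma-membrane proteins: localization of raw camera stacks,
super-resolution rendering, pair-correlation cluster analysis that
separates fluorophore blinking from true protein clustering, membrane
density quantification, and a production/degradation model of membrane
protein turnover under competitive transient transfection.

The package is aimed at microscopists and image analysts who need the
*numbers* behind super-resolution images — densities per µm², cluster
sizes, precision estimates, turnover rates — together with a synthetic-data
module that provides ground truth for validating every stage.

## The science in brief

**Localization.** Sparse single-molecule frames are background-corrected
(sliding temporal median), candidate peaks are detected and fitted by
nonlinear least squares to a symmetric 2D Gaussian, and each event's
localization precision is

σ_loc = FWHM / √N = 2√(2 ln 2) · σ_fit / √N,

with N the detected photons. Stage drift is estimated by redundant
cross-correlation of temporally binned reconstructions and subtracted.

**Pair-correlation cluster analysis.** The radial autocorrelation g(r) of
the localization pattern is estimated by FFT on a binned count image with
mask-based edge correction. Repeated blinking of a single fluorophore
produces an artifactual short-range term

g_stoch(r) = exp(−r²/4σ²) / (4πσ²ρ),

so g(r) is fitted to two nested models — random, g = g_stoch + 1, and
clustered, g = g_stoch + (A e^{−r/ξ} + 1) ⊛ g_PSF — and a nested-model
F-test decides whether genuine clustering is present. ξ, the correlation
length of the exponential cluster term, is the operational cluster size.

**Density and turnover.** Membrane density is quantified as localized
events/µm² averaged over 5 regions of interest per cell (mean of means),
normalized to an untransfected control, and compared across groups by
one-way ANOVA. A membrane protein produced at rate P and degraded at rate
k = ln 2 / t_half follows

D(t) = (1 − P/k) e^{−kt} + P/k,

so a measured relative density D at time t inverts in closed form to the
production/degradation ratio P/k = (D − e^{−kt}) / (1 − e^{−kt}); the
difference between total and exogenous percentages quantifies the
competition against endogenous expression.

## Worked example

```python
import smlmq

k = smlmq.rate_from_halflife(40.0)            # 0.017329 per hour
smlmq.solve_production_rate(1.63, 41.0, k)    # 2.2387...
smlmq.solve_production_rate(1.79, 41.0, k)    # 2.5533...
d = smlmq.decompose_competition(163.0, 79.0)
d.endogenous_pct                              # 84.0
d.endogenous_reduction_pct                    # 16.0
```

Read: a membrane pump with a 40 h half-life measured at 163% of control
density 41 h after transfection implies a summed production/degradation
ratio of 2.24; had the endogenous production been untouched the exogenous
79% would have pushed it to 2.55 — the shortfall means the endogenous
contribution fell to 84% of control, a 16% reduction by competition.

Running `python examples/03_pair_correlation.py` on a simulated clustered
acquisition prints

```
g(r) at first bin: 7.2 (CSR baseline is 1)
random model:    sigma = 25.1 nm, RSS = 12397.2
clustered model: A = 17.73, xi = 19 nm, sigma = 15.8 nm, RSS = 10151.4
selected: clustered (F = 10.5, p = 7.54e-05)
```

i.e. the blinking-only model cannot explain the correlation and the fitted
cluster correlation length is ~19 nm. The other scripts under `examples/`
cover simulation, raw-stack localization, density quantification with
ANOVA, rendering and axial profiles, and kinetics.

A thin CLI mirrors the stages (`smlmq simulate|localize|render|density|
paircorr|axial|kinetics`, each with `--seed/--config/--out`).

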