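# violacap

How many butterflies can a patch of host plants feed?

`violacap` estimates the larval carrying capacity of a site for
*Speyeria adiaste clemencei*, an imperiled fritillary of the southern
California Coast Ranges, from belt-transect surveys of its only local
host plant, *Viola purpurea quercetorum*, and lab measurements of how
much leaf a larva eats before pupating. It is written for conservation
ecologists who want to ask either "does the host present explain the
adults we count?" or, in reverse, "how much *Viola* does a target
population need?".

## The model

Four field quantities are treated as random variables and fitted by
maximum likelihood:

| quantity | data | fitted family |
|---|---|---|
| violet density per m² (by ≤30 m transect segment) | many exact zeros | mixture: point mass *w* at 0 + Exponential(λ) |
| leaves per plant | counts ≥ 1 | log-normal(μ<sub>log</sub>, σ<sub>log</sub>) |
| leaf area per leaf (mm²) | positive | gamma(shape, rate) |
| leaf area consumed to pupation (m²) | positive | Weibull(shape, scale) |

Candidate families (normal, log-normal, left-truncated normal, gamma,
Weibull) compete by AIC = 2k − 2ℓ̂; the zero-inflated mixture is compared
to a pure exponential with a likelihood-ratio test. A Monte Carlo then
propagates the fitted distributions: each of 10,000 iterations draws a
mean density (average of 1,000 mixture draws, which avoids zero-violet
iterations), one value each of leaves per plant, leaf area and
consumption, and computes

    leaf area present [m²] = A · D · L · S        pupae = leaf area present / C

with site area A, density D (m⁻²), leaves per plant L, leaf area per
leaf S (converted mm² → m²) and per-larva consumption C (m²). On top of
this the package sweeps fixed densities 0.010–0.100 m⁻² and regresses
median pupae on density, and computes a distribution-aware alternative:
count the 30-m segments that individually hold enough plants to feed one
larva (≥ 10 at average leaf metrics) and scale by the sampled fraction
of the site.

## Worked example

The headline run uses the fitted parameters reported for the 2013 Chews
Ridge survey (`violacap.presets`): density mixture with mean 0.037 m⁻²,
leaves ~ lognormal(2.05, 0.792), leaf area ~ gamma(3.00, 0.0151) mm²,
consumption ~ Weibull(6.53, 0.027) m², site area 243,206.5 m².

```python
from violacap import SimConfig, run_simulation, summarize, percentile_rank
from violacap.presets import (TOTAL_AREA_M2, density_mixture, leaves_fit,
                              leafarea_fit, consumption_fit)

config = SimConfig(reference_area_m2=TOTAL_AREA_M2, seed=1)
sample = run_simulation(config, density_mixture(), leaves_fit(),
                        leafarea_fit(), consumption_fit())
print(summarize(sample))
print(percentile_rank(sample, 227))
```

Running `python examples/02_capacity_simulation.py` (the same
computation) prints:

```
pupae supported over 243,206.5 m^2 (10,000 iterations):
  mean       796
  median     486   (q25 240, q75 967, q95 2534)

adult mark-release-recapture estimate 227 (95% CI 146-392) sits at the
23.3th percentile of the simulated distribution (CI endpoints at 12.2% and 41.6%)
```

The distribution is strongly right-skewed: the site's host biomass most
plausibly feeds a few hundred pupae, occasionally a few thousand, and the
independently estimated adult population (227) sits near the first
quartile — the plant *present* could feed more larvae than were observed,
so access to the plants, not their total biomass, is the tighter
constraint. The other scripts in `examples/` walk through distribution
fitting, the density sweep (slope ≈ 13,200 pupae per unit density,
r² ≈ 0.996), the segment-level capacity (371 pupae), and an end-to-end
synthetic-data self-check.

A thin CLI exposes the same stages
(`violacap synth|fit|simulate|sweep|segments|recover`); every run writes
a manifest JSON with its seed and configuration.

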