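# atne

Eco-evolutionary simulation of fishing-induced evolution in a lake food web:
an **A**llometric **T**rophic **N**etwork with **E**volution.

## What this is for

Size-selective fishing does not just remove biomass — it selects on the
growth trajectories of fish. This package simulates that process at the food
web level, for scientists studying fisheries-induced evolution. A
guild-structured pelagic web (phytoplankton → zooplankton → planktivorous
fish → piscivorous fish) is driven by an allometric trophic network (ATN)
model, and two focal fish species carry evolving von Bertalanffy growth
traits — asymptotic length L∞ and Brody's growth coefficient k — on a
discrete genotype grid. Gillnet- and trawl-shaped selectivity curves remove
biomass preferentially at certain body lengths, shifting the trait
distributions across generations.

## The model in brief

**Growth.** Individual length follows the von Bertalanffy growth model
L(a) = L∞ − (L∞ − L0)·e^(−k·a). Observed lengths at fractional age scatter
lognormally with mean equal to the curve; the Bayesian fit
(`atne.growth.fit_bvbgm`) samples the posterior of (L∞, k, L0, σ) under
uniform priors with an ensemble MCMC sampler.

**Selectivity.** Gear selectivity over length is the scaled bell
Ŝ(L | μ, σ, δ) = δ/(√(2π)σ) · exp(−(L−μ)²/2σ²), fitted to
catch-biomass-by-1-cm-length-class data by multi-start Nelder-Mead least
squares (`atne.selectivity.fit_selectivity`). The per-length instantaneous
fishing mortality is E · Ŝ(L)/Ŝ(μ), with E the peak mortality (1/year).

**Food web.** During a 90-day growth season, guild biomasses follow ODEs:
logistic producers sharing a carrying capacity, and consumers/fish feeding
through a Hill-type multispecies functional response, with metabolic rates
scaling allometrically as x ∝ (carbon body mass)^(−1/4). Fish grow along
their von Bertalanffy curves within the season, pay maintenance fm·x·B,
allocate reproductive biomass into separately tracked pools, and lose biomass
to fishing. Off season, fish decay with a halved maintenance coefficient.

**Inheritance.** After each season the reproductive pools spawn. Offspring of
a parent pair (t₁, t₂) on the (L∞, k) grid are bivariate-normal around the
pair midpoint with covariance Ω^{1/2} Λ Ω^{1/2}, where
Ω = c_V·diag((t₁−t₂)²/2) + diag(σ̃²_L∞, σ̃²_k) and Λ carries the trait
correlation ρ (negative by default: fast growers stay small). The larvae
trait distribution is the pair-probability-weighted mixture of these kernels,
discretised over the grid via the bivariate normal CDF. Heritability is
tracked as H = V_G/V_P from the larvae distribution with and without the
additive phenotypic component.

## Worked example

```python
from atne.growth import VBGMParams, fit_bvbgm, posterior_summary
from atne.synthetic import gen_length_at_age

truth = VBGMParams(l_inf=87.0, k=0.124, l0=1.7)      # a pikeperch-like fish
data = gen_length_at_age(truth, sigma=0.1, n=500, seed=3)
post = fit_bvbgm(data, seed=1)
print(posterior_summary(post).round(4))
```

prints

```
          mean      sd  ci_lower  ci_upper    rhat         ess
param
l_inf  85.8514  2.0949   82.5713   89.5170  1.0065  14660.3847
k       0.1267  0.0051    0.1183    0.1350  1.0063  13584.7140
l0      1.7187  0.1779    1.4251    2.0083  1.0069  14696.5678
sigma   0.0982  0.0031    0.0932    0.1035  1.0023  17689.7761
```

— the posterior means recover the generating parameters (L∞ within 1.5%,
k within 3%), the 90% credible intervals cover the truth, and split-chain
R̂ ≈ 1 confirms the chains mixed.

A whole eco-evolutionary experiment (100-year unfished burn-in, then 100
years of trawl + gillnet fishing at a shared peak mortality E) runs from the
shell:

```bash
atne simulate --out runs/fished --grid 40x40
atne report --runs runs/fished --reference runs/control
```

or from Python via `atne.simulate.run_scenario` on the built-in toy web
(`atne.synthetic.toy_foodweb`). Under trawl selection centred above the
planktivore's mean length, the planktivore's L∞ distribution shifts towards
smaller values relative to the unfished control — the classic signature of
fishing-induced evolution towards smaller asymptotic size.

## Layout

| module | contents |
| --- | --- |
| `atne.growth` | von Bertalanffy evaluation, fractional age, Bayesian fit |
| `atne.selectivity` | bell-curve evaluation/fitting, catch aggregation |
| `atne.foodweb` | ATN ODE core: guilds, links, season integration, off-season |
| `atne.evolution` | trait grid, inheritance kernel, spawning, ageing, heritability |
| `atne.simulate` | scenario driver, sensitivity suites, reporting |
| `atne.synthetic` | synthetic data generators and the toy food web |
| `atne.cli` | `atne` command-line interface |

See `docs/methods.md` for the modelling choices, numerical methods and
limitations.
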