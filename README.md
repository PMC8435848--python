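# diadino

Simulation and inference for diatom–dinoflagellate competition experiments
in semi-continuous culture.

Marine diatoms and dinoflagellates respond differently to warming and
nutrient enrichment, and shifts between the two groups propagate into the
elemental (C:N:P) and lipid (fatty acid, sterol) composition of the
particulate pool.  A standard way to quantify the competition is a bi-algal
culture experiment: grow each species alone and together across a factorial
design of temperature × N:P supply ratio × nutrient concentration, dilute
the cultures daily by a fixed fraction, and fit a Lotka–Volterra model to
the density time series.  `diadino` implements that entire analysis as a
tested, reusable library — including a synthetic-data generator that
emulates the full 3 × 3 × 3 design with triplicates, so every stage can be
exercised and validated without wet-lab data.

## The model

Densities `N1` (diatom) and `N2` (dinoflagellate), in 10⁴ cells mL⁻¹,
follow competitive Lotka–Volterra dynamics

    dN1/dt · 1/N1 = r1 (K1 − N1 − α N2) / K1
    dN2/dt · 1/N2 = r2 (K2 − N2 − β N1) / K2

where `r` and `K` are the monoculture growth rate and carrying capacity and
`α` (`β`) scales the per-capita effect of the dinoflagellate on the diatom
(and vice versa).  `α > 0` means the dinoflagellate holds the competitive
superiority, `α < 0` the diatom, `α = 0` neither.

Semi-continuous culturing replaces a fraction `D = 1 − e^(−μt)` of the
volume daily, with the gross growth rate target `μ` set to 20 % of the
batch maximal growth rate `μ_max` and `t = 1 d`.  At steady state the net
growth rate `r = μ − D ≈ 0`: growth exactly balances dilution, so the daily
per-capita rate `g_i = ln(N_i(t+1)/N_i(t)) − ln(1 − D)` estimates the
growth term of the equations above.  With `(r, K)` fixed from monoculture
logistic fits, each interaction coefficient is linear in the daily-rate
regression and has a closed-form least-squares solution.

Downstream, the package computes the composition indices that proxy the
community (molar POC/PON and PON/POP, 16:1n-7/16:0, EPA/DHA, and the sterol
fraction B/(B+D)), and the statistical layer used to interpret them:
fixed-effects GLMs compared by AICc (a ≥ 10-unit improvement rule),
penalized cubic-spline additive models with GCV-chosen smoothness for the
amplitude of the nitrate effect on `α`, and ordinary least-squares
regressions of composition on cell-ratio.

## Worked example

```python
from diadino import (
    CommunityParams, simulate_batch, simulate_semicontinuous,
    renewal_rate, gross_growth_target, estimate_mu_max,
    per_capita_rates, estimate_interaction, classify_superiority, GrowthFit,
)

params = CommunityParams(r_diatom=0.8, r_dino=0.45, K_diatom=120, K_dino=50,
                         alpha=0.6, beta=0.3)

# monoculture batch curve -> mu_max -> daily renewal fraction
mono = simulate_batch(CommunityParams(0.8, 0.45, 120, 50, 0, 0), 0.5, 0.0, 20)
mu_max = estimate_mu_max(mono, species="diatom").mu_max
D = renewal_rate(gross_growth_target(mu_max))
print(f"mu_max = {mu_max:.3f} d^-1, D = {D:.4f}")

# biculture: batch to early stationary phase, then 20 d semi-continuous
batch = simulate_batch(params, 0.5, 0.5, 12)
n_last = batch.df.iloc[-1]
semi = simulate_semicontinuous(params, (n_last.n_diatom, n_last.n_dino), D, 20)

series = per_capita_rates(semi, D)
est = estimate_interaction(
    series,
    GrowthFit(mu_max=mu_max, window=(0, 0), r=0.8, K=120),
    GrowthFit(mu_max=0.4, window=(0, 0), r=0.45, K=50),
)
print(f"alpha = {est.alpha:.3f} +/- {est.alpha_se:.3f}  "
      f"beta = {est.beta:.3f} +/- {est.beta_se:.3f}  (n = {est.n_points})")
print("superiority:", classify_superiority(est.alpha))
```

Output:

```
mu_max = 0.787 d^-1, D = 0.1456
alpha = 0.600 +/- 0.000  beta = 0.300 +/- 0.000  (n = 19)
superiority: dinoflagellate
```

The simulated biculture was generated with `α = 0.6`; the estimator
recovers it from the daily densities alone, and the positive sign reads as
dinoflagellate superiority for this parameter set.

## Command line

```sh
diadino simulate --seed 1 --out fixture/          # synthetic experiment -> CSVs
diadino fit-growth --input fixture/               # monoculture (r, K) fits
diadino fit-interaction --input fixture/          # alpha, beta per biculture
diadino composition --input fixture/              # stoichiometric/lipid indices
diadino run-all --seed 1 --out report/            # generate + fit + stats + report
```

`run-all` writes `interaction.csv`, `indices.csv` and `stats_report.json`
(AICc model selection per response, per-temperature spline summaries, and
the composition-vs-community regressions).  Runs are byte-deterministic
under a fixed seed.  Configuration can be supplied as YAML (`--config`);
recognised keys and defaults are listed in `docs/methods.md`.

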