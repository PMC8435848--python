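# Methods

This note records the modelling choices behind `diadino`: what is
simulated, how the estimators work, which constants are built in and why,
and what the synthetic data can and cannot tell you about real cultures.

## Experimental design and renewal arithmetic

The design module encodes a 3 × 3 × 3 factorial: temperatures 12/18/24 °C,
N:P molar supply ratios 10:1, 24:1 and 63:1, and three nutrient levels
whose nitrate/phosphate concentrations (μmol L⁻¹) are stored exactly as in
the medium recipe (e.g. 35.2/3.6 at the low 10:1 cell, 4 400/180 at the
high 24:1 cell).  Silicate is 880 μmol L⁻¹ everywhere so that it never
limits the diatom.  Culture volume is 200 mL; each treatment has three
replicates.  The recorded molar N:P of every cell is within 3 % of its
label, and construction validates a 5 % band.

Semi-continuous renewal replaces the fraction `D = 1 − e^(−μt)` of the
culture volume per renewal interval `t` (1 d throughout), with the gross
growth-rate target `μ` set to 20 % of the batch maximal growth rate.  `D`
is a dimensionless fraction per day; the protocol convention treats it
interchangeably with a loss rate in `r = μ − D`, which is exact at steady
state (`r = 0`) and accurate to first order in `μ` otherwise
(`|D − μ| ≤ μ²/2` at `t = 1`).  We implement the convention literally and
expose both `renewal_rate` and `net_growth_rate`.

## Dynamics

Bicultures follow competitive Lotka–Volterra dynamics (see README for the
equations), integrated by fixed-step classical RK4 with a default step of
0.01 d.  The system is smooth and non-stiff at the growth rates of
interest (≤ ~1.2 d⁻¹); step-halving changes day-resolution densities by
< 10⁻⁶ relative, and the α = β = 0 limit agrees with the closed-form
logistic to ~10⁻¹⁰.  Daily renewal is modelled as an instantaneous event
multiplying both densities by `1 − D` (the replacement medium is
cell-free), not as a continuous outflow — matching a protocol in which a
volume fraction is exchanged once per day.  Negative densities can only be
produced by gross step sizes; they are clamped to zero with a logged
warning, never silently.

A density below 10⁻⁶ (in 10⁴ cells mL⁻¹) is treated as absent.  This
detection floor mimics the hemocytometer limit and protects the log-scale
estimators from zeros.

Steady state is declared on the earliest day whose trailing window
(default 5 d) of post-dilution densities has a coefficient of variation
below 5 % for every species above the floor; a washed-out species cannot
hold the culture out of steady state.

## Growth and interaction inference

**μ_max** is the slope of ln(density) vs day over the contiguous batch
window (≥ 4 points) maximizing R², with ties broken toward longer, then
earlier, windows.  A perfectly flat window counts as R² = 1 so a
non-growing culture yields μ_max = 0 rather than an arbitrary window.

**(r, K)** come from a nonlinear least-squares fit of the closed-form
logistic to the monoculture batch curve (free parameters r, K, n₀;
initialised at the μ_max estimate, the maximum observed density and the
first observation; up to five jittered restarts; asymptotic SEs from the
Jacobian).

**Per-capita rates.**  Daily counts are taken before dilution.  The gross
per-capita rate over the interval [t, t+1] is
`g = ln(N(t+1)/N(t)) − ln(1 − D)`; the correction restores the dilution
loss so that `g = μ = −ln(1 − D)` holds exactly at steady state.  The
uncorrected variant (plain log difference) is retained behind a flag for
sensitivity analyses.  Days on which either species is at or below the
detection floor are excluded and logged.

**Interaction coefficients.**  With (r, K) fixed from the monocultures,
the daily-rate identity `g1 = r1 (K1 − ⟨N1⟩ − α ⟨N2⟩) / K1` is linear in α
(and symmetrically in β), where ⟨·⟩ is the within-interval time-average
density.  The first pass approximates ⟨N⟩ by the logarithmic mean of the
interval endpoints (exact for exponential within-day growth); subsequent
passes integrate the fitted model within each day from the observed start
states and re-solve, a fixed-point refinement that removes the endpoint
quadrature bias (noiseless recovery error ~10⁻³ over α ∈ [−2, 3] versus
~10⁻¹ for the endpoint approximation alone).  Least squares — not
averaging of the point-wise inversions — is the primary estimator because
it is linear, closed-form and lower-variance; the point-wise diagnostics
`α_t = (K1 (1 − g1/r1) − N1)/N2` are reported alongside.

Standard errors use a Newey–West (lag-1) sandwich: consecutive daily rates
share a count, so the residuals are serially correlated and the i.i.d.
formula would overstate the variance.  In simulation with Poisson counting
noise (≥ 200 expected cells/day), nominal 95 % intervals cover the truth
in ~91–95 % of runs and the mean bias of α̂ is below 0.01.

Superiority is classified by the sign of α (positive → dinoflagellate,
negative → diatom, within ±tol → neutral).

## Composition indices

Molar POC/PON and PON/POP, the fatty-acid ratios 16:1n-7/16:0 (the n-7
isomer specifically) and EPA/DHA (20:5n-3 / 22:6n-3), and the sterol
fraction B/(B+D) = brassicasterol/epi-brassicasterol over its sum with
dinosterol.  Ratios with zero denominators are flagged missing (NaN), not
zero-filled — zero-filling would bias the downstream regressions.  B/(B+D)
is computed on per-litre concentrations because it is correlated with
cell-count fractions; carbon-normalised analyte concentrations
(μg (mg C)⁻¹) are exported in parallel since either convention is
defensible for the community-proxy figures.  "Major" fatty acids are those
strictly exceeding 5 % of total FAs.

## Statistical layer

**GLMs.**  Responses (α and the five composition indices) are modelled on
numeric factors — temperature (°C), N:P molar ratio, nitrate (μmol L⁻¹) —
with candidates of first order, first + second order, and the full
third-order interaction.  The named-effects structure contains no random
terms, so these are fixed-effects GLMs (statsmodels IRLS); the default
family is Gaussian-identity, with Gamma-log selectable per response in the
configuration because strictly positive ratio responses can warrant it.
`k` counts the regression coefficients plus the dispersion parameter.

**Model selection.**  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).  The lowest-AICc
model is chosen only if it improves on every simpler candidate by ≥ 10
units; otherwise the simplest candidate wins unless a more complex model
contains an interaction term with p < 0.05, in which case the best such
model is chosen.  The decision is invariant to candidate order.
Significance is p < 0.05 throughout.

**Additive model.**  The amplitude analysis fits a penalized cubic
B-spline of α on nitrate concentration: basis size 10 (interior knots at
quantiles of the unique x values), second-derivative penalty integrated
exactly by two-point Gauss–Legendre per knot interval, and smoothing
parameter minimizing `GCV = n·RSS/(n − edf)²` over a 40-point log-spaced
grid scaled to the data (spanning effectively unpenalized to effectively
linear).  The solver uses the Demmler–Reinsch orthogonalisation, which
makes `edf = Σ 1/(1 + λ sᵢ)` stable at any λ and gives the exact λ → ∞
limit edf = 2 (the penalty null space of lines).  The reported p-value for
the smooth is an approximate F-test against a constant fit.  Models are
fitted per temperature and jointly; the response amplitude is max − min of
the centred partial effect over the observed nitrate range.  On noiseless
linear data the smoother reproduces the line (deviance explained = 1); on
pure noise the GCV choice collapses toward the null space (median deviance
explained ~1–2 %).

**OLS.**  Composition-vs-community couplings use simple least squares:
PON/POP, 16:1/16:0 and EPA/DHA against the diatom/dinoflagellate cell
ratio, and B/(B+D) against the diatom fraction of total cells.

## Synthetic data: what it emulates

The generator produces, for every treatment × replicate, a diatom
monoculture, a dinoflagellate monoculture and a biculture: a batch phase
until the trigger species (the diatom, except in dinoflagellate
monocultures) first shows daily log-growth below 0.05 d⁻¹ ("early
stationary"), then 25 d of semi-continuous culture with D derived from the
latent batch μ_max, then a steady-state composition sample.  All
ground-truth constants live in `synthetic.py`:

- **Growth.**  r_diatom peaks at 18 °C (0.47–0.94 d⁻¹ across levels),
  r_dino increases toward 24 °C (0.27–0.57 d⁻¹); K values scale with the
  nutrient level (diatom 45/130/280, dinoflagellate 16/45/90 ×10⁴ cells
  mL⁻¹).  These are invented but sit in the ranges routine for these taxa
  in enriched-seawater culture.
- **Interaction surface.**  α(T, x) = a₀(T) − a₁(T)·log₁₀x +
  a₂(T)·max(0, log₁₀x − 3.2)² with a₂ > 0 only at 24 °C.  The surface is
  positive (dinoflagellate superiority) at the low nutrient level,
  negative (diatom superiority) at the high level for 12/18 °C, and turns
  positive again at 24 °C at the very highest nitrate; its amplitude over
  the design's nitrate span decreases strictly with temperature.  β is a
  weak function of temperature only (0.24–0.36).
- **Chemistry.**  Per-cell quotas give the diatom the lower N:P
  (90/8 ≈ 11 vs 330/16 ≈ 21 fmol cell⁻¹), and the lipid signatures give it
  the 16:1n-7, EPA and brassicasterol enrichment (dinosterol is exclusive
  to the dinoflagellate, brassicasterol to the diatom, so the sterol
  fraction hits both end-members exactly).  Treatment modifiers scale the
  N quota up with nutrient level and (at the two lower levels) with the
  supply N:P ratio, scale the P quota up faster at high nutrients (luxury
  P uptake), and scale diatom EPA with temperature — reproducing the
  qualitative response patterns of the indices without altering the
  mixing signal that links composition to community structure.

**Noise model.**  Hemocytometer counting is Poisson: a density of
N ×10⁴ cells mL⁻¹ counted over `counting_volume` μL (default 2) yields an
expected count of 10·N·volume cells, and the observed density is
count/volume.  Optional multiplicative lognormal terms add day-to-day
process variability (CV 5 %) before counting and per-analyte analytical
error (CV 8 %) to the chemistry.  Defaults reflect a few hundred cells
counted per sample and typical elemental/GC-FID precision.  Post-dilution
densities are derived volumetrically from the daily count rather than
re-counted, as in practice.  Randomness derives from one seed split
hierarchically per (treatment, culture type, replicate) stream, so any
unit can be regenerated independently and runs are bit-reproducible.

**What passing tests do not show.**  The latent dynamics are exactly
Lotka–Volterra with constant coefficients: real cultures add nutrient
drawdown within the day, allelopathy, photoacclimation, wall growth and
time-varying interaction strengths, none of which are modelled.  Parameter
recovery on this generator therefore validates the estimator pipeline
(identifiability, bias, calibration), not the adequacy of the
Lotka–Volterra description for any particular experiment.  Likewise the
composition model is a two-end-member mixing model with independent
multiplicative noise; it cannot probe physiological covariance between
growth state and quota.

## Problem sizes and numerical choices

Default runs use the full 27-treatment design with triplicates (81
bicultures, 162 monocultures), ~15–25 batch days plus 25 semi-continuous
days per unit, at RK4 step 0.01 d; the complete pipeline executes in a few
seconds on one CPU because all units integrate in one vectorised sweep.
Monte-Carlo characterisations (noisy recovery, coverage, null smoother
behaviour) use 200 replicates; the composition-coupling study uses 100
generated experiments.  Interval-mean refinement uses 4 fixed-point
iterations at an inner step of 0.02 d, converging to < 10⁻¹⁰ movement in
practice.  Exactly-zero penalty eigenvalues are enforced below 10⁻¹⁰ of
the largest so that heavy smoothing limits to the linear fit.

## Configuration keys

YAML accepted by the CLI / `PipelineConfig` (unknown keys are rejected):
`mode` (synthetic | csv), `input_dir`, `seed`, `noiseless`, `replicates`,
`counting_volume` (μL, default 2), `process_cv` (0.05), `chemistry_cv`
(0.08), `dilution_corrected` (true), `family_per_response` (mapping
response → gaussian_identity | gamma_log), `basis_size` (10), `out_dir`.

## Known limitations

- The GLM layer deliberately omits random effects; with triplicate
  pseudo-replication inside treatments the p-values are anti-conservative
  relative to a mixed model.
- The GAM p-value is an approximate F-test, not the exact distribution of
  the GCV-selected smoother; treat it as indicative.
- The interaction estimator conditions on monoculture (r, K) as known;
  their sampling error is not propagated into α̂'s interval (in simulation
  the effect on coverage is small at batch-curve noise levels).
- Exclusion of days below the detection floor truncates washout
  trajectories; α̂ for strongly excluding pairs rests on the early
  semi-continuous days.
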