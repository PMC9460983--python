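# Methods

This note documents the model implemented in `peatflux`, the constants it
fixes, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Process model

**Canopy.** Stomata are assumed to maximize carbon gain minus the water
cost λ·E over the day, which at steady state gives the closed form

E = 1.6 D g_σ, g_σ = (√[(C_a − R/f(I)) / (1.6 λ D)] − 1) f(I),

clamped at zero: stomata are closed whenever the respiration burden R/f(I)
exhausts the CO₂ gradient or the water price 1.6λD exceeds what is left.
The light response f(I) = ιγI/(ιI + γ) saturates at γ; its initial slope
ι = max{c(S − S₀), 0} is gated by the acclimation state S, a first-order
low-pass filter of leaf temperature (dS/dt = (T_l − S)/τ) that encodes
spring recovery and autumn shutdown of photosynthetic capacity.
Leaf temperature is T_l = T + 1.5·10³ I and respiration
R = R₀·Q₁₀^(T_l/10).

**Belowground.** All soil water states derive from water table depth δ (cm)
through a van Genuchten retention curve
θ(δ) = θ_res + (θ_sat − θ_res)/[1 + (0.072 δ)^1.371]^(1−1/1.371).
The soil-to-root conductance is segmented: a rising power law
k_sr⁺ = ξ_m (θ/θ_sat)^ξp (water limitation at depth), a falling power law
k_sr⁻ = η_m ((2θ* − θ)/θ_sat)^ηp (hypoxia under waterlogging, with
θ* = θ(δ*) recomputed from the current δ* at every evaluation), and a
plateau k_sr* equal to the mean of k_sr⁺[θ(δ*+10 cm)] and
k_sr⁻[θ(δ*−10 cm)], held over the 20 cm band around the optimal depth. The
realized conductance is the pointwise minimum of the three. In series with
the constant per-tree root-to-leaf leg k_rl = max{J}/(ρ|Ψ_lmin|) it gives
k_sl, and the marginal water-use efficiency follows the log-log-linear
bridge log₁₀λ = z₀ + z₁ log₁₀(k_sl/k₀) with z₁ < 0. The hypoxia branch is
deliberately heuristic: η_m and η_p lump aquaporin, respiration and
soil-gas effects; no mechanistic oxygen-diffusion model is attempted.

**Error model.** Residuals ε = E_obs − E_model (with E_obs = J/ρ) are
zero-mean normal with a standard deviation that grows with the modelled
rate: SD = exp(α + β_W1·E_model) for the W1 tree group (trees 4 and 6 by
default) and SD = β_W2·E_model for the W2 group. The SD is floored at
10⁻⁸ mol m⁻² s⁻¹ so the density stays proper when the modelled rate
reaches zero.

## Estimated parameters and priors

All priors are independent uniform boxes; per-tree parameters share one box.

| parameter | meaning (unit) | box |
|---|---|---|
| ξ_m,i | rising-branch multiplier, per tree (mol m⁻² s⁻¹ Pa⁻¹, pre-scale) | 0.07–0.15 |
| ξ_p | rising-branch exponent | 7–10 |
| η_m | falling-branch multiplier (pre-scale) | 0.05–0.17 |
| η_p | falling-branch exponent | 1.5–10 |
| δ* | optimal water table depth (cm) | 20–50 |
| z₀, z₁ | λ–k_sl bridge intercept and slope | −5.2…−3.8, −1.0…−0.5 |
| c_i | acclimation slope, per tree (m³ mol⁻¹ °C⁻¹) | 0.01–0.07 |
| γ | light-response saturation (m s⁻¹) | 1.6–3.0 ×10⁻³ |
| α, β_W1 | semi-log error intercept/slope | −15–0, 0–50 |
| β_W2 | proportional error slope | 0–1 |
| λ_i (RM1 only) | constant water price, per tree | 10⁻³–10⁻² |

The error-model and RM1-λ boxes are not published anywhere; they are wide,
centred on the magnitudes the data model implies, and exposed in config.

The full model has 22 parameters; RM1 replaces the belowground block with
six constant λ_i (16 parameters); RM2 drops η_m, η_p and δ* (19).

## Fixed constants

Whole-tree conversion: leaf-to-sapwood area ratio ρ = 2500 m² m⁻² and
isohydric minimum leaf water potential Ψ_lmin = −2 MPa, both standard for
Scots pine and held constant across trees and years.

Canopy constants (S-model literature values, overridable in the `canopy:`
config block): R₀ = 10⁻⁶ mol CO₂ m⁻² s⁻¹, Q₁₀ = 2, S₀ = 5 °C, τ = 7 days,
C_a = 0.0167 mol m⁻³ (≈405 ppm at 20 °C).

Soil constants (`soil:` block): a_vg = 0.072 cm⁻¹ and n_vg = 1.371 fix the
retention shape. The remaining four constants — θ_sat, θ_res, the base-case
xylem conductance k₀, and the single scale factor that converts the ξ_m/η_m
prior-box magnitudes to per-leaf-area conductance — are not published as
numbers; they are, however, tightly pinned by the published per-tree curve
summaries (the plateau-conductance range 2.72–3.55 ×10⁻⁹ mol m⁻² s⁻¹ Pa⁻¹,
the λ range at the optimum 3.94–5.73 ×10⁻³, and the decline-onset span
33.4–39.3 cm under the published MAP calibration). A one-off solve against
those summaries gives θ_res/θ_sat ≈ 0.123 and yields the defaults
θ_sat = 0.88, θ_res = 0.108 (typical of drained peat),
scale = 9.31·10⁻⁷ and k₀ = 2.22·10⁻⁸ mol H₂O m⁻² leaf s⁻¹ Pa⁻¹; with them
all three summary ranges are reproduced within 0.6%. The scale factor is
applied exactly once, when a parameter vector is decoded, so the unit
conversion is auditable in a single place.

## Inference

The posterior is sampled with an ensemble of walkers using an 80/20 mixture
of differential-evolution and snooker proposals (`emcee`), which handles
the strong correlations and hard box bounds of this posterior well.
Walkers start from independent prior draws; everything is reproducible from
the seed. Only the second halves of the chains are retained for the
Gelman–Rubin diagnostic, the MAP (the retained draw with the highest
log-posterior), the marginal 2.5/97.5% credible intervals and the
predictive bands. Convergence is declared at R̂ < 1.1 for every parameter;
a run that does not reach it is flagged on the result object, never
silently accepted, and a fully stagnated ensemble (mean acceptance < 1%)
aborts with a diagnostic. Predictive 95% bands are pointwise 2.5/97.5%
quantiles of E_model + ε over 6000 parameter vectors resampled from the
retained posterior, with one heteroscedastic error draw per tree-day each.

Default desk-scale budgets: 48–64 walkers × 1200–3000 steps. At these
budgets the R̂ < 1.1 bar is typically not yet met on the 22-parameter
problem — the ensemble is still mixing — but the posterior mass is already
well located: on the recovery scenario the credible intervals cover the
generating values for ≥ 80% of parameters and the MAP reproduces the
well-identified subset (z₀, z₁, γ, c_i) within a few percent. Longer runs
sharpen R̂ without changing those conclusions.

## Synthetic scenarios

The generator emulates only the statistical structure the calibration
needs, not site meteorology: temperature and humidity are seasonal
sinusoids plus AR(1) noise, irradiance is a seasonal clear-sky envelope
times beta-distributed cloudiness, and the water table follows piecewise
linear within-season waypoints (snowmelt waterlogging → drawdown through
the optimal band → late-summer drought) with AR(1) jitter, clamped at the
surface. Generated daily values stand directly for the top-decile-median
daily statistic of the reduction pipeline. Observations are forward-model
output at an interior "truth" vector plus group-wise heteroscedastic noise;
negative draws are clamped at zero and the clamp rate is reported, since
the clamp slightly biases the noise where the modelled rate is near zero
(tests that probe the noise structure therefore condition on
E_model > 2·10⁻⁴).

Bundled scenarios: `tiny` (3 trees × 40 days, smoke tests), `recovery`
(6 trees × 4 seasons × 184 days — the identifiability scenario), `regime_sweep`
(slow monotone water-table ramp) and `waterlogged` (waterlogging-heavy
seasons that still visit the plateau and dry regimes, used for the
reference-model comparison). Scenario truth values sit in the interior of
every prior box; the six nominal maximum sap-flow densities from the
published site table serve as realistic tree metadata. The fixtures write a
`trees.csv` carrying those nominal maxima so that the generating and the
fitted model share the same k_rl; deriving k_rl from the noisy synthetic
maximum instead would inflate it by the largest noise excursion and bias
the bridge parameters. For real data, where the observed maximum *defines*
k_rl, the dataset builder recovers j_max from the observations when no tree
table is given.

What passing these tests shows: the pipeline is internally consistent — the
calibration machinery recovers parameters from data that satisfy the
model's own assumptions, and the predictive bands are correctly calibrated
against the assumed error model. What it does not show: robustness to real
sensor artefacts, seasonally varying ρ or Ψ_lmin, water-table spatial
heterogeneity, or error structure beyond the heteroscedastic normal.

## Numerical and design choices

- **Daily reduction**: the per-day statistic is the median of the
  ⌈0.1 n⌉ largest values (ceiling guarantees a non-empty set for any
  n ≥ 1), applied identically to D, I, T, T_l, δ and J. Days missing any
  driver are dropped, never imputed.
- **WTD anchoring**: the logger trace supplies the temporal pattern; the
  sparse manual tube readings supply the level, via a linearly
  interpolated additive offset that passes exactly through every manual
  point (held constant beyond the ends; a single manual point degenerates
  to a constant shift). Multiple tubes are averaged per timestamp into one
  site-level series. Negative depths (standing water) are clamped to 0.
- **Acclimation**: forward Euler at Δt = 1 day; the state restarts at each
  season's first leaf temperature (seasons are split at data gaps > 30
  days), with an optional N-day spin-up repeat of day 1. Since τ is a fixed
  constant, the S series is precomputed once per dataset.
- **Guards**: f(I) < 10⁻¹² counts as closed stomata; the square-root
  argument and g_σ are clamped at 0; the k_sr⁻ base is clamped at 0 for
  θ ≥ 2θ* (keeps non-integer powers real; unreachable for δ* within its
  prior box on this retention curve); E(D=0) = 0.
- **RM2** uses the uncapped rising branch — the minimal monotonic change
  from the full model. A config alternative (`rm2_cap: ksr_star`) retains
  the plateau cap, in which case RM2 shares the full layout.
- **Zero-intercept R²** is reported in the centered convention
  1 − SS_res/Σ(y−ȳ)², the one comparable with ordinary regression R²; the
  uncentered convention is available behind a flag. The shallow-WTD subset
  is δ < δ*−10 cm using the fitted δ* of the evaluated full-model run (the
  reference models have no δ* of their own).
- **Ties** in the MAP search break to the first retained draw; identical
  chains report R̂ = 1 when the within-chain variance is zero.
- Per-tree day masks (NaN in the observation matrix) carry trees with
  discarded periods through the likelihood without imputation.

## Known limitations

The hypoxia branch is phenomenological; water-table temperature, which
correlates with residuals in the reference system, is not an input; ρ,
Ψ_lmin, and the canopy constants are global; sub-daily dynamics and carbon
budget outputs are out of scope. Ensemble-sampler R̂ across walkers is an
optimistic convergence measure compared with independent long chains.
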