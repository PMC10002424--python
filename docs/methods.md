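# Methods

This note documents the models, algorithms and numerical choices behind
`cropcal`, in the spirit of a package's own methods documentation: what
is computed, under which assumptions, and where the genuinely open
design decisions were made.

## 1. The calibration problem

A layered soil–crop system over one spring-maize growing season (sowing
April 12, harvest October 18, 190 days inclusive) at an arid oasis site:
annual precipitation around 116 mm, potential evaporation roughly twenty
times larger, flood irrigation per one of four treatments (standard
irrigation 5 × 150 mm = 750 mm, conserving 105/105/120/120/120 = 570 mm;
urea-N 138 or 92 kg/ha applied at the first scheduled date).

45 parameters are calibrated simultaneously, all with uniform box
priors:

* **Hydraulic (32):** `Ks` (cm/d), `SAT`, `FC`, `PWP` (cm³/cm³) for each
  of 8 layers. The canonical vector ordering is (Ks, SAT, FC, PWP) per
  layer for layers 1..8 — this ordering defines index semantics for
  every ensemble matrix and chain in the package.
* **Nitrogen transformation (5):** maximum nitrification rate `Vn`
  (g/(m³·d), [5, 15]), nitrification half-saturation `Kn` (g/m³,
  [25, 75]), denitrification ratio `Kd` ([0.5, 1.5]), denitrification
  empirical constant `Ad` ([0.05, 0.15]), ammonia-volatilization rate
  `Kv` (1/d, [0.015, 0.045]).
* **Crop (8):** crop coefficients `Kini` [0.36, 0.54], `Kmid` [1, 1.5],
  `Kend` [0.64, 0.96]; thermal time to maturity `Tsum` (°C·d,
  [1480, 2220]); specific leaf areas `SLAmax` [24, 36], `SLAmin`
  [8, 12] (m²/kg); maximum assimilation rate `AMAX` (kg/(hm²·h),
  [36, 54]); maximum root depth `Rmax` (cm, [96, 144]).

The hydraulic bounds were checked during transcription: in every layer
`PWP.upper < FC.lower < SAT.lower`, so every vector inside the prior box
binds to a physically ordered profile (0 < PWP < FC < SAT < 1). The
forward model still validates the ordering and signals invalid vectors
(possible for user-supplied spaces) with NaN predictions, which the
samplers treat as infinite misfit.

Observations are volumetric soil water content θ (cm³/cm³) on 17 listed
days after sowing at either 16 depths (20–170 cm every 10 cm; the
synthetic layout, 272 points) or a split layout: 8 depths
(20,40,...,160 cm; 136 points) for calibration and 7 held-out depths
(30,50,...,130,170 cm; 119 points) for validation — 150 cm is unused, as
in the original design. Measurement error is homoscedastic Gaussian,
sd 0.005 cm³/cm³, diagonal covariance C_D; perturbed values are never
clipped, so C_D remains the exact error model the samplers assume.

## 2. The surrogate forward model

The package deliberately does not re-implement a full
Richards-equation/C-N-cycle simulator. The surrogate is a daily
tipping-bucket cascade chosen so that (a) every one of the 45 parameters
is consumed, (b) the water balance closes to machine precision, and
(c) one season simulates in well under a millisecond per ensemble member
(the season loop is vectorized across members).

**Discretization.** The 180 cm profile is split into 8 equal layers of
22.5 cm (layer thickness is a convention; the original profile's layer
geometry is not published). A measurement depth d cm maps to layer
⌈d / 22.5⌉, boundaries belonging to the layer above. Time step: 1 day,
explicit, no sub-daily iteration.

**Water.** Each layer holds water `θ·dz`. Daily, in order: (1) rain +
irrigation enter layer 1; storage above `SAT₁·dz` becomes surface
runoff; (2) cascade top → bottom: storage above field capacity drains to
the next layer at a rate capped by `Ks` (cm/d); storage above saturation
is passed on uncapped (porosity is a hard ceiling), bottom drainage
leaves the profile; (3) evapotranspiration (below). Layers start the
season at field capacity. The daily ledger (input, ET, drainage, runoff,
storage change) closes to < 1e-9 cm by construction — property-tested.

**Evapotranspiration.** Potential crop ET is `Kc(gdd)·ET0·g`, where `Kc`
is the FAO-56-style piecewise-linear curve over thermal time: `Kini` up
to 0.2·Tsum, linear rise to `Kmid` at 0.45·Tsum, plateau to 0.75·Tsum,
fall to `Kend` at Tsum. Growing degree days use base 8 °C over a fixed
sinusoidal annual temperature cycle (arid continental amplitude); since
truth generation and calibration share the cycle, its exact shape is
immaterial. The demand multiplier `g = max(0.5, AMAX·(SLAmax+SLAmin)/2
/ (54·24))` is a crude, bounded leaf-area proxy that gives the remaining
crop parameters a weak smooth influence; the mean of the two SLA bounds
is used so that `SLAmin` is consumed too, normalized by the upper prior
bounds. 30% of potential ET evaporates from layer 1 (limited by its
storage); 70% is transpiration distributed over the root zone
(root depth grows linearly in thermal time to `Rmax`) proportionally to
plant-available water `(θ − PWP)⁺·dz`, and capped by it per layer.

**Nitrogen.** Single ammonium/nitrate pools (initial 5 and 20 g/m³,
fertilizer converted over the 180 cm profile) stepped daily:
nitrification `Vn·NH₄/(Kn+NH₄)`, volatilization `Kv·NH₄` (jointly capped
at the pool), denitrification `Kd·Ad·NO₃·s(θ₁)` with `s` rising linearly
from 0 at FC to 1 at SAT. Nitrogen has **no feedback on water**, so the
soil-water observation vector is bit-identical under any nitrogen
parameter perturbation. This is intentional: it reproduces the
weak identifiability (and hence multimodal nitrogen posteriors) that the
water-content-only calibration design implies, and it is property-tested.

**What the surrogate is not.** No Richards flow, no heat transport, no
crop growth/yield, no CO₂ response. Passing tests demonstrate the
*samplers'* behavior under a realistic parameter-to-observation map;
they say nothing about the predictive skill of the simplified physics on
real field data.

## 3. Synthetic data generation

One root seed spawns independent streams for weather, the reference
parameter draw and measurement noise; the whole pipeline is
bit-reproducible. Weather: rainfall on sparse random days (12%
frequency, gamma amounts), rescaled so the seasonal total matches the
season's share (~52%) of the 116 mm annual precipitation with ±20%
seeded variation; reference ET follows a summer-peaked cycle rescaled so
ΣET0 = 20 × Σprecip, the site's aridity ratio. Reference truth is a
prior draw pushed through the surrogate; observations add i.i.d.
N(0, 0.005²) noise.

## 4. Samplers

**Kalman gain.** `K = C_MD (C_DD + C_D)⁻¹` with 1/(Ne−1) sample
covariances, computed by Cholesky solve (never explicit inversion), with
a 1e-10 trace-scaled ridge for safety; genuinely singular systems raise.

**ES update.** Each member assimilates its own perturbed observation
`dⱼ ~ N(d, α·C_D)` (fresh draws per member per iteration). Updated
vectors that leave the prior box are *reflected* back at the walls —
reflection preserves ensemble spread where clipping would pile mass onto
the bound; the folding map is an isometry, and a paired-count test
verifies it preserves proposal symmetry.

**ES-MDA.** Sequential ES updates with inflation factors αᵢ. The
consistency condition enforced is Σ 1/αᵢ = 1 (constant schedule αᵢ = n
by default, n = 3 for the study protocol). A variant normalization
Σ 1/αᵢ² = 1 appears in parts of the literature; it is available behind
`MDASchedule(..., squared_constraint=True)` but is not the default, as
only Σ 1/αᵢ = 1 makes the linear-Gaussian case exactly consistent with a
single update — which the test suite verifies against the closed-form
posterior.

**ILUES.** Per iteration and per member j: rank all members by
`J = a·J₁/J₁ᵐᵃˣ + b·J₂/J₂ᵐᵃˣ` where `J₁ = (d−f(m))ᵀ C_D⁻¹ (d−f(m))` and
`J₂ = (m−mⱼ)ᵀ C_MM⁻¹ (m−mⱼ)` (C_MM the ensemble parameter covariance);
take the N_L = α·N_e smallest; Kalman-update that local set with local
covariances and fresh perturbed observations; replace member j by a
uniformly random member of the updated local set; re-simulate everyone.
Open choices, fixed as: weights a = b = 1 (never published), local
fraction α = 0.1 (N_L = 50 at N_e = 500), J₁ᵐᵃˣ/J₂ᵐᵃˣ taken over the
candidate set being ranked, no error-covariance inflation inside ILUES
(a flag enables MDA-style inflation). All are exposed in `ILUESConfig`.

**DREAM-ZS / KZS.** N chains (default 3) propose jumps from an archive Z
of past states, initialized with 10·d prior draws and appended with all
chains' states every 10 generations (the archive never contains the
proposing generation's current states). Moves:

* *parallel direction* (p = 0.7): θᵖ = θ + (1+e)·γ(δ,d′)·Σ(z_a − z_b) +
  ε on a CR-selected coordinate subset; δ ∈ {1,2,3}, CR ∈ {⅓,⅔,1}
  uniform (the full adaptive-pCR machinery is out of scope),
  γ = 2.38/√(2δd′), unit jumps (γ = 1) every 5th generation; e, ε small
  seeded perturbations.
* *snooker* (p = 0.1): jump along the line through θ and an archive
  point z with γ_s ~ U(1.2, 2.2) and Metropolis correction
  (‖θᵖ−z‖/‖θ−z‖)^(d−1).
* *Kalman* (p = 0.2, KZS only, only while t ≤ T_k = 0.2·T):
  θᵖ = θ + K(d − f(θ) + ε), ε ~ N(0, R), K estimated from the archive's
  parameter/prediction pairs. The move is asymmetric; rather than pay a
  proposal-density correction (which would erase its efficiency gain),
  it is confined to the first T_k generations and *all* samples with
  t ≤ T_k are discarded as burn-in. Metropolis steps during that phase
  use the uncorrected ratio — an approximation inherited with the
  design, which is why those samples never enter posterior summaries.

The likelihood is independent Gaussian with R = noise_sd²·I (exposed in
config) plus the uniform-prior box indicator; proposals are reflected
into the box. Default burn-in for posterior summaries is max(T/2, T_k).
Outlier-chain correction is disabled by default (3 × 1000-generation
chains are too short for the IQR test to be meaningful). Diagnostics:
acceptance rate by move type, per-parameter Gelman–Rubin R̂ on the
post-burn-in halves, per-generation per-chain RMSE series.

One root seed spawns independent per-chain streams; runs are
bit-reproducible per platform.

**MAP convention.** Ensemble methods carry no posterior density, so the
MAP member is the one with maximal Gaussian log-likelihood (equivalently
minimal J₁); `RMSE_MAP` is the RMSE of its prediction against the
(noisy) observations, and is re-computable bit-exactly from serialized
results.

**Uncertainty bands.** Pointwise central 95% quantiles of the posterior
predictions (parameter band), and of predictions plus one fresh noise
draw each (total band). Whether the original figures used pointwise
central quantiles is not stated; this is the convention here. The total
band is forced to nest the parameter band (the union is taken) so
finite-sample quantile noise cannot invert the by-definition nesting.

**Marginal summaries** use Freedman–Diaconis binning with a degenerate
single bin for constant samples.

## 5. Study-condition defaults and problem sizes

The synthetic experiment protocol is: truth from the prior, 272
observation points, noise sd 0.005, ensemble 500, 3 iterations — these
are the package defaults (`ExperimentConfig()`); `desk_scale()` halves
the ensemble and chain length for interactive use. The MCMC comparison
uses the mixture (0.7, 0.1, 0.2), T_k = 0.2·T, 3 chains, 1000
generations at full scale on the 136-point calibration layout.

The test suite runs the burn-in-acceleration comparison at 300
generations over 10 seeds: the observed contrast is extreme (KZS median
first-passage below √2·noise_sd within ~10 generations; ZS typically
censored at the horizon), so the shorter horizon does not affect the
verdict, and it keeps the suite fast. Oracle tests use a 2-parameter
linear-Gaussian model at ensemble 2000 (Monte-Carlo error of ensemble
estimators is measured from 8 independent replicates, since sampled
gains and perturbed observations add variance beyond sd/√Ne; MCMC error
uses autocorrelation-based effective sample size).

**Bimodal toy.** f(m) = m², observation 4.0 ± 0.5, prior U[−5, 5]; the
dense-grid posterior is exactly symmetric with modes at ±2. The
comparison uses ensemble 50 with an 8-step schedule: with a perfectly
symmetric prior the global ES-MDA gain is near zero at few iterations
and the ensemble barely moves, so the methods' divergence only becomes
visible over more assimilation steps, where ES-MDA's globally coupled
updates commit it to one mode. A mode counts as "populated" when it
holds ≥ 20% of members — less than half its true 50% posterior share.
ILUES keeps both modes near 50/50 in every seed; ES-MDA drops one mode
below that bar in over 80% of seeds.

**Coverage.** The 8 most output-sensitive hydraulic parameters (by
prior-ensemble correlation screening these are FC of all 8 layers —
storage starts at FC and drains back to it, so FC dominates the
observed θ) are checked for 95%-interval coverage of the synthetic truth
across 10 seeds. The ES-MDA posterior is used for this check: its global
linear-Gaussian update yields approximately calibrated marginal spread
(~94% coverage observed), whereas ILUES deliberately trades calibrated
Gaussian spread for the ability to represent multiple modes — its random
local-adoption step contracts marginals, and its intervals under-cover
(~75%) on this unimodal-truth benchmark. That trade-off is inherent to
the method pair, not a defect of either implementation.

## 6. Known limitations

* The surrogate's physics are intentionally minimal; absolute RMSE
  levels on real field data would be dominated by structural error that
  the synthetic benchmark cannot exhibit.
* Field-measured soil-water data and the original simulator are not
  available, so the practical-case "calibrate on 136 / validate on 119"
  design is exercised with synthetic truth only; published real-data
  misfit values are out of reach by construction.
* DREAM here fixes CR ∈ {⅓, ⅔, 1} rather than adapting crossover
  probabilities, and implements no multi-try or tempering variants.
* The weather generator produces one season of daily forcing with a
  deterministic temperature cycle; it does not emulate inter-annual
  variability, frost events, or sub-daily rainfall intensity.
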