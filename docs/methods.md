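# Methods

## Model structure and assumptions

The berry is one well-mixed compartment behind a composite membrane whose
exchange area grows with fruit surface area (*A*
= γ·FW^η, γ = 5.2076 cm² g⁻η, η = 0.6424). Four states evolve: water *w*,
dry matter *s*, starch *u* (all g) and turgor *P_f* (bar). Key assumptions:

- Whole-fruit density is 1 g cm⁻³, so volume, fresh weight and the cube of
  relative diameter are used interchangeably.
- All sugar concentrations are mass fractions (g solute per g solution);
  osmotic pressure is van 't Hoff with sucrose equivalents
  (π = R·T·C·ρ_sol/M_s + π_other, R = 83.14 cm³ bar mol⁻¹ K⁻¹,
  M_s = 342 g mol⁻¹), with constant non-sugar baselines π_pO = 12.53 bar
  (phloem) and π_fO = 6.5 bar (fruit).
- Soluble-solids percentage is reported on juice mass (water + soluble
  solids), matching how refractometer measurements are made in the field.
- Stem phloem is in local water equilibrium with stem xylem
  (P_p = Ψ_x + π_p). The same closure is imposed at the fruit end
  (P_p′ − π_p′ = Ψ′), which makes the pedicel mass balance linear in Ψ′.
  This closure is isolated in one module so an alternative is a drop-in.
- Internal air-space humidity is 0.996; saturation vapour pressure uses the
  Buck equation (6.1121·exp(17.502·T/(240.97+T)) hPa), accurate to <1%
  over 0–40 °C.
- Fruit temperature equals air temperature.

## Prescribed developmental trajectories

Several coefficients follow fixed functional forms of fruit age *t* (days
after full bloom, DAFB) or size. Where only anchor properties of a curve
are known, the simplest form satisfying all of them was adopted and pinned
behind the module interface:

- **Wall extensibility** φ(*t*): ln φ piecewise-linear — plateau φ₁ = 0.2
  bar⁻¹ h⁻¹ to d₁ = 15 d, log-linear to φ₂ = 0.00135 bar⁻¹ h⁻¹ at
  d₂ = 60 d, then declining at φ_k = 0.0028 d⁻¹ (natural log, since φ_k
  pairs with an exponential decline). An alternative reading of these two
  constants (φ₂ = 0.000135, φ_k = 0.028) is selectable by plain override;
  it produces smaller, higher-dry-matter fruit with late turgor near
  12 bar, but the shipped defaults are kept as primary.
- **Pedicel xylem conductance**: double-logistic
  L₂ₓ + (L₁ₓ−L₂ₓ)·σ(k₁ₓ(t−t₁))·(1−σ(k₂ₓ(t−t₂))) with L₁ₓ = 0.09,
  L₂ₓ = 0.02 g h⁻¹ bar⁻¹, k₁ₓ = 0.1, k₂ₓ = 0.036 d⁻¹, t₁ = 30, t₂ = 70 d:
  rises, peaks after day 40, levels off late — using exactly the six
  fitted constants.
- **Pedicel phloem conductance**: single logistic Lp∞·σ(k₁p(t−t₁)) with
  Lp∞ = 0.016 g h⁻¹ bar⁻¹ and k₁p = k₁ₓ so both conductances grow in
  concert early; phloem function never declines.
- **Skin permeance**: ρ∞ + (ρ₀−ρ∞)·exp(−k_ρ(t−t_ρ)) for t ≥ t_ρ = 18 d
  (held at ρ₀ = 800 cm h⁻¹ before the first anchor), ρ∞ = 25 cm h⁻¹,
  k_ρ = 0.035 d⁻¹.
- **Starch synthesis coefficient**: k_s(t) = k_s1·(1−exp(−(t_r−t)/t_h))
  for t < t_r, else 0 — continuous, non-increasing, slow-then-fast, zero
  at t_r = 165 d, and exactly (1−1/e) ≈ 63% of k_s1 = 0.5 d⁻¹ at
  t_r − t_h = 140 d.
- **Maximal active uptake**: ν_m = ν₁·s·Q10^((T−20)/10), ν₁ = 0.005 h⁻¹,
  Q10 = 2, referenced to 20 °C.

## Starch / soluble-solids partition

Structural matter is an exponentially reducing proportion of dry weight,
o = A_o·s·exp(−k_o·s) (A_o = 0.56, k_o = 0.0384 g⁻¹), capped so that o,
starch and a basal soluble-solids requirement (s_b = 3.8% of fresh weight)
never exceed s; soluble solids are the remainder s_s = s − o − u, floored
at zero with a logged warning rather than an abort, because early-season
states can transiently violate the partition. The alternative saturating
form A_o·(1−exp(−k_o·s)) and a juice-mass basis for the cap are selectable
but rejected as defaults (the saturating form yields implausibly small
structural mass).

## The pedicel sucrose flux convention

The sucrose carried by the pedicel phloem is modelled as the sap flow F_p
times a concentration. Two conventions are implemented; the default is the
**mean** of stem and fruit-end concentrations, (C_p + C_p′)/2. The
downstream-only alternative (F_p·C_p′) is selectable but not default for a
structural reason worth recording: with the base conductance Lp∞ = 0.016
g h⁻¹ bar⁻¹ and Münch pressure differences of order 10 bar, sap flow is
capped near 0.15 g h⁻¹. Under a purely downstream-weighted flux the
fruit-end concentration collapses toward zero once dry mass exceeds ~2 g
(demand ν_m/K_m outruns the supply slope), sugar import then *falls* as
ν₁ rises, and crop-load and uptake-sensitivity signs invert relative to
the documented behaviour. The mean weighting — physically, a dispersive
contribution of the upstream sap — restores a self-consistent regime in
which all sign patterns hold.

## Respiration

Maintenance + growth respiration: R = q_m·Q10_r^((T−20)/10)·s + q_g·(growth).
Growth respiration proportional to net growth is resolved in closed form,
ds/dt = (uptake − maintenance)/(1+q_g) when uptake exceeds maintenance.
The constants q_m = 4.44e-4 g g⁻¹ h⁻¹ (20 °C), q_g = 0.084, Q10_r = 1.9
come from the peach-fruit modelling lineage this model extends; they live
only in the shipped parameter file, never in code.

## Synthetic environment

The generator produces the four hourly drivers from a compact, fully
deterministic configuration:

- Seasonal envelopes of daily T_max, T_min, H_max, H_min and the daily
  transpiration total are order-2 Fourier series in calendar day. The
  shipped coefficients are **illustrative**, hand-set once for a Southern
  Hemisphere season (bloom on calendar day 325, latitude −37.8°): mean
  January-to-May cooling ≈ 7 °C, summer transpiration several-fold above
  autumn, peak midday stem water potential near −8 bar. They are not fitted
  to any weather record, so simulated magnitudes are not comparable to
  specific field seasons — only shapes, signs, conservation and limit
  properties carry over. Anything quantitative in the test suite therefore
  avoids depending on them.
- Within a day, temperature follows a sine-exponential curve (sinusoidal
  rise from T_min at sunrise, peak lagged 1.8 h after the day-length-scaled
  midpoint, exponential night decay with shape constant 2.2), with day
  length from latitude and date. Humidity is antiphase between its own
  extrema. Envelopes are evaluated on the integer day, so the daily
  extrema anchor exactly; the resulting O(0.05 °C) jump at midnight is
  documented and harmless at the half-hour step.
- Transpiration is a sin² daytime pulse whose integral equals the daily
  total; stem water potential is Ψ_x = P_soil − Tr/L_soil_stem with
  P_soil = −1 bar (well-watered) and L_soil_stem = 0.001 L s⁻¹ bar⁻¹.
- Phloem sucrose tracks the diurnal temperature pattern between 9% and 17%
  (g/g); a crop-load offset lowers it uniformly (0.01 g/g for the
  high-crop scenario).
- Input-sensitivity experiments shift only the daily extrema of one input,
  preserving the diurnal shape.

A CSV-driven environment (linear interpolation, schema-validated) replaces
the generator when measured series are available.

## Numerics

- **Integration**: classical RK4, fixed step, default 0.5 h, outputs every
  1 h. The pedicel algebraic system is re-solved at every RK4 stage (a
  semi-explicit DAE treatment) because turgor changes on sub-hour scales.
  Non-finite states or solver failures abort with the last valid state.
  States are floored at 1e−6 g with abort-on-floor.
- **Pedicel solve**: mass balance eliminated in closed form (linear in
  Ψ′); sugar balance solved for C_p′ by Brent iteration on [0, 1.5·max(C_p,
  C_f)] with xtol = 1e−14, ≤200 iterations, residuals recorded. When no
  non-negative root exists (possible very early while the pedicel phloem is
  nearly non-conducting), the bracket extends into (−K_m, 0) where the
  active-uptake pole guarantees a sign change; such solutions are flagged
  `out_of_range`, not fatal. Accepted residuals are at machine level
  (≲1e−15 g h⁻¹, contract ≤1e−9).
- **Time units**: internal rates are per hour; the starch sub-model's
  per-day rates are divided by 24 at the assembly boundary only.
- **Book-keeping**: cumulative flux integrals are accumulated with the same
  RK4 stage weights as the state update, so conservation checks test the
  wiring, not quadrature luck.
- **Step-size accuracy**: the elastic turgor equation has a fast scale
  ε·φ ≈ 30 h⁻¹ while φ is on its early plateau, outside RK4's stability
  region at the default step whenever P_f exceeds the yield threshold.
  The integration remains bounded (the yield clamp prevents blow-up) and
  self-convergent at observed order ≈ 3, but carries a few-percent state
  error before day ~40 at the 0.5 h step, diluting to ≈0.2% in harvest
  fresh weight; from a day-40 restart, step-halving agreement is ~1e−6.
  Users needing resolved early-season turgor should use steps ≤ 0.1 h.
- **Rigid-wall variant**: for ablation studies and as the ε→∞ reference,
  a pure-Lockhart mode treats turgor algebraically, solving net inflow =
  plastic expansion per stage (Brent, bracket expansion); a scalar
  extensibility refit (secant, ≤2 iterations) compensates overall growth
  when comparing against the elastic model.

## Test problem sizes

Season-long checks run the default 170-day, half-hour-step configuration
(two scenarios shared session-wide). The pedicel solver is verified against
a nested grid-refinement oracle on 100 random valid states; limit checks
use ×1e6 conductances (zero-resistance) and ε = 1e5 bar over a 2-day window
at a 0.005 h step (stiff reference). Convergence order is measured on a
10-day window (days 20–30) at steps 1.0/0.5/0.25 h.

## Known limitations

- Early in the season the starch sub-model over-accumulates starch and
  depresses soluble solids, which in turn lets diurnal turgor swing
  negative — a recognized weakness of this sub-model family, not corrected
  here.
- Harvest-day magnitudes under the shipped defaults (e.g. fresh weight far
  above a field kiwifruit) reflect the illustrative weather and the
  permissive default extensibility tail; the alternative extensibility
  constants give field-like magnitudes at the cost of one crop-load sign
  property. Both are one override away.
- Single compartment: no apoplast/symplast split, no membrane leakage with
  ripening, no whole-vine feedback; phloem sap composition other than
  sucrose is a fixed osmotic baseline.
- The pedicel has no storage or lateral leakage; xylem backflow is allowed
  (and does occur around midday under the defaults).
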