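# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `hazrisk`, and what the synthetic test bed
does and does not demonstrate.

## Model assumptions

1. **Point source, instantaneous onset.** The vehicle overturns and leaks
   immediately; the spill is a point source spreading in all directions.
   The default conditional leakage probability is therefore the overturn
   entry (0.375) of the accident-type table; a subset of accident types can
   be combined by summation (they are mutually exclusive), capped at 1.
2. **No degradation, equal amounts.** The released chemical neither decays
   nor adsorbs during diffusion, and the *same* total amount Q is used for
   every water medium (the amounts are not split between media).
3. **Segment independence.** An accident on one segment does not affect
   the population or environment of any other; network records are simply
   the per-segment records, and route risk is their sum.
4. **Hourly periods.** Time-varying inputs are 24-period profiles, one per
   hour of day, with no sub-hour interpolation.

## Probability model

`P_ij(t) = 1e-6 · P^A · P^B · M_ij(t) · L_ij/2`. The `L/2` factor treats
the tabled vehicle density as two-directional traffic on an undirected
segment; an `use_length_squared` override (`L²` in place of `L/2`) is
provided for sensitivity analysis. The result is a dimensionless
probability, not clamped at 1 — realistic urban inputs give 1e-6..1e-4 —
but a warning is emitted if it exceeds 1.

## Dispersion and geometry

* **Plume.** The risk chain uses the ground-level centreline form
  `C(x) = Q^Hazard/(π a b v x^(c+d))`; the full 3-D plume with ground
  reflection is implemented for completeness but not used in scoring. The
  threshold radius is the exact closed-form inverse, so zone radii are
  monotone decreasing in both threshold and wind speed, and zone nesting
  (r₁ ≥ r₂ ≥ r₃) follows from the AEGL ordering invariant enforced at
  scenario construction.
* **Stability parameters.** The package ships Pasquill–Gifford classes A–F
  as smooth power-law fits in SI metres (`plume.PASQUILL_GIFFORD`),
  converted from the classic rural curve fits tabulated for x in km; the
  small additive offsets of the original σ_z fits are dropped. These are
  screening-level approximations; a CSV override (`class,a,b,c,d`) is
  supported, and all tests use explicit simple parameters so no table
  choice affects correctness.
* **Water media.** The advection–dispersion radii use a lateral dispersion
  coefficient 0.58 for surface water and a transverse mixing coefficient
  0.145 in the river far-bank term; each additive term is in metres and
  each log argument dimensionless. Radii are clamped at zero from below: a
  log argument < 1 means the limit concentration is never exceeded beyond
  the source, outside the model's validity regime.
* **Volumes.** Air and groundwater pollution occupy hemispheres
  `(2/3)πr³`. Lake/river volumes depend on the road/water relation:
  `alongside` → quarter sphere `(1/3)πr³`, `crossing` → hemisphere. The
  elapsed diffusion times (t^Gwater, t^Lake, t^River) are scenario-level
  constants — an assessment horizon — distinct from the hour-of-day index,
  which only selects flow/wind profile values. The default horizon is
  3600 s, one assessment period.

## Costs and bearing capacity

* **Population.** Four per-person cost types (evacuation, inspection,
  medical, casualties) with a zone-by-type incidence matrix α_uv(t). The
  shipped default incidence is illustrative: it rises with zone severity
  (nearly universal medical need in the innermost AEGL-3 zone, mostly
  evacuation/inspection in the outer AEGL-1 ring) and is constant over t.
  Default unit costs (500 / 300 / 5 000 / 1 500 000 CNY) are
  documentation-level placeholders, not calibrated prices.
* **Environment.** Per-m³ emergency-disposal, monitoring and remediation
  costs per medium, with water media an order of magnitude costlier than
  air. Currency is an opaque unit; no conversion logic exists.
* **Capacity ratios.** The population ratio divides the exposed population
  by that of a corridor `10³·L·d^Pop` at the same density (d^Pop = 600 m,
  the emergency-response isolation guideline); the density cancels
  algebraically, but a zero density leaves the ratio undefined — the
  low-level function raises, and the assessment pipeline short-circuits to
  p = 0, q = 0.9 (the consequence is zero there, so the score is
  unaffected). The environmental ratio divides Q by `Σ_r V_r·C_r`; it is
  undefined (error) only if every volume is zero, which cannot happen in
  the pipeline since the air volume is always computed.
* **Preference exponent.** q(p) follows the printed brackets exactly,
  including boundaries: p = 0.5 → 0.9, p = 1 → 1.0, p = 1.5 → 1.05.
  `ER = P·C^q` is evaluated in the log domain to avoid overflow for large
  consequences with q > 1. Because `C^q` is unit-sensitive (for C < 1 the
  transform reverses direction), scores are comparable only within one
  currency unit system; ER^Pop and ER^Env are reported separately and
  never summed into one number.

## Synthetic study conditions

The generator emulates a simplified suburban district: 38 nodes and 52
arcs on a jittered grid with a nearest-neighbour spanning tree plus short
chords (connected, planar-ish; coordinates are synthetic decoration).
Study conditions:

* **Traffic.** Gaussian rush-hour bumps at 08:00 and 18:00 over a daytime
  base (defaults 15 → 55 veh/km), with ±5% jitter small enough that every
  segment's peak stays in a rush-hour period.
* **Population.** Land-use archetypes at an urban scale of 0.01 persons/m²
  (10 000/km²): residential higher at night, commercial higher in the
  daytime, boarding schools flat, mixed in between.
* **Wind and flows.** Diurnal sinusoids with afternoon maxima; means 3 m/s
  (wind), 0.3 m/s (river) and 0.003 m/s (groundwater) with ±50% swing —
  the two-orders-of-magnitude speed separation that drives the
  medium-variation ordering air > river > groundwater > lake (lakes are
  static, so their volume is exactly constant over the day).
* **Scenario.** 6 t of gaseous ammonia; the release duration converting
  the load to a plume feed rate is a modelling choice (default 600 s →
  10⁷ mg/s). Ammonia thresholds are illustrative config, not regulatory
  data: the public 60-min AEGLs converted to mg/m³ (21 / 111 / 766) and
  water limits in the spirit of ambient ammonia-nitrogen standards
  (500 / 1000 / 1000 mg/m³).

All randomness flows through one seeded numpy generator; a fixed seed
gives byte-identical networks. Water-body coverage (each medium, both
road/water relations) is guaranteed by a post-pass on the first few
segments.

**What passing tests show — and don't.** The synthetic bed demonstrates
the model's qualitative behaviours (rush-hour probability peaks, inverse
wind–consequence relation, lake time-invariance, the medium-variation
ordering) and exact agreement with hand-composed arithmetic oracles. It
does not validate against real traffic, population, meteorology or price
data, spatial correlation between neighbouring segments, or any real
network geometry.

## Numerical conventions

* Internal units: km for segment length (entering formulas through
  explicit 10³ factors), otherwise m / s / mg / mg·m⁻³; population density
  persons/m² (a `normalize_population_density` helper converts from
  persons/km²).
* Zero clamps are applied to water radii only; zone areas are non-negative
  by construction.
* The environmental capacity sum runs over the four defined media.
* CSV output uses full-precision `repr` floats; identical inputs reproduce
  byte-identical outputs.

## Known limitations

* Steady-state plume only: no puff (instantaneous-release) model, plume
  rise, deposition or terrain effects.
* Screening-level hydrology: no 2-D/3-D transport, adsorption, tides or
  degradation kinetics.
* The incidence matrix and cost tables ship as illustrative defaults and
  should be replaced with local data for any real study.
* No routing or optimisation: the package scores networks and routes, it
  does not choose them.
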