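# Methods

## Scope and model structure

`acidnit` models the *abiotic* fate of nitrite in an acidic ammonia-oxidation
CSTR. Biology enters in exactly one place: a prescribed fraction `f_ox` of
the influent ammoniacal nitrogen is converted to nitrite (the observed
nitritation, ≈50% when alkalinity is the limit — two protons are released
per mol N oxidized, so a 1:1 molar alkalinity:TAN ratio supports conversion
of only half the TAN). Everything else — pH, dissolved oxygen, temperature,
conductivity — is an exogenous *driver* read from an operation timeline,
never a solved state. There is no charge balance, no alkalinity ODE, no
biomass growth. This mirrors how such reactors are analysed when the
question is whether chemistry alone explains the observed nitrate and
nitrogen losses, and it keeps the model falsifiable: given measured drivers
the chemistry either reproduces the nitrate series or it does not.

## Speciation

Free ammonia and free nitrous acid are computed from the totals with
Henderson–Hasselbalch using conditional constants:

- pKa(NH₄⁺) = 0.09018 + 2729.92/T[K] (≈9.25 at 25 °C),
- pKa(HNO₂) from ln Ka = −2300/T[K] (≈3.35 at 25 °C).

Ionic-strength effects use the Davies equation (A = 0.509, linear term
0.3), applied only to the charged partner of each pair; pH is interpreted
as hydrogen-ion activity (a glass-electrode reading), so no correction is
applied to H⁺. Both choices are the standard ones in the nitrification
literature; the coefficients are configurable through
`SpeciationConstants`. Ionic strength may be supplied directly or estimated
from conductivity with the empirical linear rule I ≈ 0.016·EC (mol/L per
mS/cm) — a rule-of-thumb for mixed electrolytes, exposed as a parameter
because urine matrices can deviate.

Conservation (free + ionized = total) holds exactly by construction because
only the fraction is ever computed; the free species are never integrated
as independent states.

## Reaction network

Mass-action kinetics in molar units, with concentrations carried in mg-N/L
and converted only inside the rate laws:

| reaction | rate law (event rate) |
|---|---|
| 2 HNO₂ → NO + NO₂ | k₂f·[HNO₂]² |
| NO + NO₂ → 2 HNO₂ | k₂r·[NO][NO₂] |
| 2 NO + O₂ → 2 NO₂ | k₃·[NO]²[O₂] |
| 2 NO₂ → HNO₂ + NO₃⁻ + H⁺ | k₄f·[NO₂]² |
| HNO₂ + NO₃⁻ + H⁺ → 2 NO₂ | k₄r·[HNO₂][NO₃⁻]·a(H⁺) |
| N₂O₃ + NH₃ → N₂ + HNO₂ | k_N₂O₃·[NO][NO₂] · K_b[NH₃]/(1+K_b[NH₃]) |

N₂O₃ is treated as a quasi-steady intermediate: it forms from NO + NO₂ and
either decomposes straight back (a null cycle with no net effect, so it is
not carried as a state) or reacts with NH₃. The saturating branching
fraction K_b[NH₃]/(1+K_b[NH₃]) interpolates between decomposition-dominated
and NH₃-dominated regimes; the branch can be disabled entirely
(`nh3_branch_enabled=False`), since the ammonia pathway is a completeness
term rather than a load-bearing one.

Default constants are per-day conversions of textbook aqueous
nitrous-acid/NOx kinetics (e.g. k₃ from the third-order NO autoxidation,
k₄f from NO₂ hydrolysis). They are shipped as *placeholders with units*,
flagged for verification against the primary literature on chemical nitrite
oxidation in acid solution (Udert et al., 2005), because the model's
structural guarantees — conservation, monotonicity, stoichiometry — are
what the test suite certifies, not these numbers. The YAML config schema
(`acidnit.io`) stores one block per reaction with id, law, reversibility
and constants-with-units, and round-trips values exactly.

Temperature corrections are Arrhenius-style factors θ^(T−25) per reaction,
default θ = 1 (off): with unverified base constants a default temperature
dependence would be false precision.

### Stoichiometry and conservation

Each reaction redistributes nitrogen across
{TAN, TNN, NO₃⁻, NO(aq), NO₂(aq), N₂} with zero sum; NO₂ hydrolysis splits
consumed NO₂-N 0.5/0.5 between nitrite and nitrate. Gas stripping moves N
from the dissolved NO/NO₂ pools into cumulative stripped-mass ledgers, and
the N₂ produced by the ammonia branch goes to a cumulative ledger as well
(it is insoluble and inert, not a concentration subject to outflow). The
N-weighted sum of all derivatives plus fluxes is identically zero, which is
why closed-system conservation tests pass at 10⁻⁶ relative and the
whole-run CSTR balance closes to solver precision.

### Gas transfer

First-order kLa stripping with zero gas-phase backpressure
(flux = kLa·C), defaults kLa = 100 d⁻¹ for both NO and NO₂ — an
order-of-magnitude figure for a vigorously aerated stirred tank. When the
DO driver falls below 0.5 mg/L the reactor is considered non-aerated and
fluxes are scaled by `aeration_off_factor` (default 0.1), representing the
collapse of bubble-driven transfer.

## CSTR simulation

For each dissolved species, dC/dt = (Q/V)(C_in − C) + source + chemistry −
stripping. The only influent species is TAN; the imposed nitritation moves
f_ox·Q·TAN_in/V from the TAN to the TNN pool. Cumulative influent,
effluent and stripped masses are integrated as extra states of the same ODE
system, so the nitrogen balance (influent = Δstorage + effluent + stripped
+ N₂) closes to integrator tolerance for *any* driver series — the balance
test is a genuine consistency check on the solver, not an identity of the
post-processing.

Driver interpolation: zero-order hold for Q, f_ox and TAN_in (pump and
control signals; TAN_in changes stepwise with feed tanks), piecewise-linear
for pH, DO, temperature and conductivity (continuous measurements).
Integration uses LSODA with rtol 10⁻⁶ / atol 10⁻⁹ and a max step tied to
the driver grid so short pump pulses are not skipped; sub-tolerance
negative excursions are clipped to zero with a logged warning. The initial
condition defaults to nitrogen-free water (start-up from a clean matrix)
and is configurable.

## Synthetic operation generator

The generator emulates the *statistical* structure of acidic
urine-nitritation operation without presupposing the chemistry under test:

- pH/pump: a two-state on–off controller. pH falls linearly (default
  0.5 pH/d) while the pump is off — standing in for biological
  acidification — and rises (default 2 pH/d) while the alkaline influent
  feeds, bouncing between the band edges (default 4.9–5.0). The pump
  magnitude is sized from the duty cycle so the mean flow delivers a target
  HRT drawn from 1.6–10 d.
- DO: a triangle wave across the 4–6 mg/L control band (period 0.02 d).
- Influent TAN: uniform steps in 1000–3500 mg-N/L at feed-tank changes
  (every 10 d by default), or a bounded random walk.
- Conductivity tracks influent strength across 15–35 mS/cm; temperature is
  flat at 25 °C plus measurement noise.
- Disturbances are injected post hoc: influent stop (Q = 0, pH relaxes
  exponentially toward a floor of 4), aeration stop (DO = 0 for 3–15 h),
  over-pumping (pH toward a ceiling of 8.5 at elevated flow), overheating
  (temperature toward 33 °C).

Defaults: 100 d at 0.01 d resolution; shorter horizons are used in tests
and in the acceptance script (1–20 d), which exercise several HRTs while
keeping runs at seconds scale. Generation is a pure function of
(config, seed).

What the generator does **not** emulate: real urine matrix variability
(COD, phosphate, carbonate), pH excursions caused by the chemistry itself
(pH is phenomenological here), sensor drift, or biology (community shifts,
VSS). Passing tests on synthetic timelines therefore certify the *model
machinery* — conservation, driver handling, metric definitions — not
agreement with any particular reactor's measured series, which exist only
as figures in the source literature.

## Metrics and activity factors

Nash–Sutcliffe efficiency E is undefined for a constant measured series and
raises rather than returning NaN. NAR and loss fractions are percentages;
the loss accounting counts dissolved N in influent and effluent, with
gas-phase N as the residual — for simulations both sides of the ledger are
available and must agree. Volumetric rates use centered finite differences
with the accumulation term included and optional moving-average smoothing
(default none). Human-readable reports round rates to integers, fractions
to whole percent and growth rates to one decimal.

The activity factors are descriptive: non-competitive K/(K+S) for HNO₂
(chosen because it reproduces the benchmark 91% inhibition at
K_I = 2.8 mg-N/L and S = 30 mg-N/L; the literature does not fix the form),
Monod terms for DO (default K_S = 0.8 mg/L) and NH₃ (default
K_S = 1 µg-N/L, the sub-µg affinity scale of acid-tolerant ammonia
oxidizers), and a threshold-linear salinity penalty above 20 mS/cm with a
free slope. They combine multiplicatively, the activated-sludge-model
convention. Two known limitations: HNO₂ toxicity is partly irreversible,
which a reversible factor cannot represent, and the observed activity drop
at pH > 8 has no established functional form, so it is deliberately left
unmodeled.

## Numerical choices

- Molar mass of N taken as 14.0067 g/mol; DO converted at 32 g/mol O₂.
- Rate-law evaluation clamps negative inputs to zero inside the RHS so the
  integrator cannot be driven out of the physical domain by round-off.
- Integrator failures raise with the last valid time and state rather than
  returning partial silence.
- Tie-break in the pH controller: the band edges are inclusive; the state
  flips exactly at the edge.

## Design decisions that were genuinely open

- The nitrite-oxidation rate constants and the ionic-strength details live
  in supplementary material of the source literature that is not machine-
  readable; the package therefore ships configurable defaults (standard
  temperature functions, Davies correction, textbook NOx kinetics) and
  keeps every tested claim independent of the unverifiable numbers.
- The imposed nitritation fraction `f_ox` supports both a scalar and a
  time series; whether the historical runs used a constant 50% or a
  TAN-tracking value is not recoverable, so both are first-class.
- The nitrogen-loss metric can be computed on cumulative mass (default in
  the simulation ledger) or from averaged concentration ratios; both modes
  are reachable through `NitrogenBalance`.
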