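# acidnit

Abiotic nitrogen chemistry of acidic ammonia-oxidation reactors.

When high-strength, alkalinity-limited liquors such as source-separated
urine (TAN up to ~3500 mg-N/L) are nitrified without base addition, the pH
settles near 5. At that pH nitrite-oxidizing bacteria are knocked out by
free nitrous acid, and nitrite chemistry takes over: HNO₂ disproportionates
to NO and NO₂, NO is re-oxidized by dissolved oxygen, NO₂ hydrolyses to
nitrite and nitrate. The net result is *abiotic* nitrate production plus
loss of volatile nitrogen oxides — exactly the signature observed in acidic
urine-nitritation reactors. `acidnit` packages the pieces needed to analyse
such systems:

- **`acidnit.speciation`** — NH₄⁺/NH₃ and NO₂⁻/HNO₂ acid–base partitioning
  with temperature-dependent pKₐ and Davies activity correction
  (γ = 10^(−A z² (√I/(1+√I) − 0.3 I))).
- **`acidnit.kinetics`** — the mass-action reaction network

  ```
  2 HNO₂        ⇌  NO + NO₂ + H₂O
  2 NO + O₂      →  2 NO₂
  2 NO₂ + H₂O   ⇌  HNO₂ + NO₃⁻ + H⁺
  NO + NO₂ (N₂O₃) + NH₃ → N₂ + HNO₂ + H₂O
  ```

  with first-order kLa stripping of NO and NO₂ and a stiff-capable
  integrator. Nitrogen is conserved exactly by construction.
- **`acidnit.reactor`** — a driven CSTR: measured flow, influent TAN, pH,
  DO and temperature are exogenous inputs, a fraction `f_ox` of the
  influent TAN (≈50% for alkalinity-limited urine) is imposed as nitrite
  production, and the chemistry decides how much ends up as nitrate or gas.
- **`acidnit.synth`** — synthetic operation timelines: on–off pH control in
  a 4.9–5.0 band, DO cycling at 4–6 mg/L, feed-tank steps, and four
  disturbance classes (influent stop, aeration stop, over-pumping,
  overheating).
- **`acidnit.metrics`** — Nash–Sutcliffe model efficiency
  E = 1 − Σ(yᵢᵐ−yᵢ)²/Σ(yᵢᵐ−ȳᵐ)², nitrite accumulation ratio
  NAR = 100·TNN/(TNN+NO₃), nitrogen-loss fractions, HRT/SRT and the washout
  growth-rate bound μ = 1/SRT, volumetric oxidation rates.
- **`acidnit.activity`** — limitation/inhibition multipliers for
  interpreting respirometric tests: non-competitive HNO₂ inhibition
  K/(K+S), Monod DO and NH₃ terms, a threshold-linear salinity penalty.

## Worked example

```python
import acidnit as an

# Free nitrous acid at urine-strength nitrite, pH 4.2, 25 °C, EC 25 mS/cm
ctx = an.IonicContext(conductivity=25.0, temperature=25.0)
print(an.free_nitrous_acid(500.0, 4.2, ctx))   # 46.82 mg-N/L

# Synthetic 20-day acidic reactor campaign
cfg = an.ScenarioConfig(duration=20.0, dt=0.02, seed=1)
tl = an.generate_timeline(cfg)
res = an.simulate(tl)
bal = res.nitrogen_balance()
print(an.nitrogen_loss_fraction(bal))          # e.g. 3.7 % of influent N
print(an.nitrite_accumulation_ratio(res.TNN[-1], res.NO3_N[-1]))  # ~85 %
```

The speciation call says that 500 mg-N/L of nitrite at pH 4.2 already means
~47 mg-N/L of free nitrous acid — past the ~40 mg-N/L level where even
acid-tolerant ammonia oxidizers shut down, which is why uncontrolled pH
drops are dangerous in these reactors. The simulated campaign shows the
typical acidic-operation fingerprint: a nitrite-dominated effluent
(NAR well above 50%) with a few percent of the influent nitrogen leaving as
NO/NO₂ gas.

The same is available from the shell:

```sh
acidnit speciate --tnn 500 --ph 4.2 --ec 25 --json
acidnit synth --seed 1 --out ops.csv
acidnit simulate --timeline ops.csv --out result.csv
acidnit metrics --timeline ops.csv --series result.csv
acidnit factors --hno2 30 --do 5 --nh3 0.04
```

A note on rate constants: the shipped defaults for the nitrite-oxidation
network are literature-sourced placeholders (see
`acidnit export-kinetics --out chem.yaml` for the configurable schema);
calibrate them against measurements before quantitative use. None of the
package's tested claims depend on their values.

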