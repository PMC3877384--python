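# isoturn

Delay-aware compartmental carbon-13 turnover analysis for animal products.

`isoturn` estimates how fast the carbon in metabolic outputs of an animal
(milk, milk components, feces) turns over, from **diet-switch experiments**:
the diet's δ¹³C is changed abruptly and the washout of the old isotopic
signal is tracked in each output. It then uses the fitted kinetics to
**forward-predict** output δ¹³C under a naturally fluctuating diet. It is
aimed at researchers in stable-isotope ecology and animal physiology who
work with δ¹³C time series (‰ vs. VPDB).

## The model

Each output stream is described by a delayed multi-pool exponential:

```
δ(t) = c + Σ_p a_p · exp(−(t − delay)/τ_p)        for t > delay
δ(t) = c + Σ_p a_p                                 for t ≤ delay  (plateau)
```

with asymptote `c` (the value on the new diet), ingestion-to-output delay
(passage time), and 1–4 pools of amplitude `a_p` and mean residence time
`τ_p`; the pool half-life is `t½ = τ·ln 2`. The **gross half-life** is the
time after the switch, delay included, at which half of the total shift is
completed — for one pool exactly `delay + t½`.

The analysis pipeline follows the experiment's logic:

1. **Delay/chase partition** — successive post-switch sampling times are
   tested against the sample at the switch with a two-sided exact Wilcoxon
   signed-rank test paired across animals; the first significant time
   starts the chase period.
2. **Joint fitting with AIC selection** — chase data from all animals are
   fitted together by nonlinear least squares (variable projection over
   log-τ with eight deterministic multistarts). Candidate pool counts and
   parameter-sharing structures (each of `c`, `a_p`, `τ_p` shared across
   animals or per-animal) are compared by AIC, with a parsimony rule when
   ΔAIC < 2 and screening of degenerate (non-identifiable) candidates.
3. **Delay refinement** — the fitted curve is intersected with the
   delay-period baseline mean; the crossing time is the refined delay
   (bracketed by the partition), and the selected model is refitted once at
   that anchor.
4. **Forward prediction** — the model defines a normalized weighting of the
   input history over a window of six half-lives of the slowest pool
   (`w(u) ∝ |Σ_p a_p e^{−u/τ_p}|`); the predicted output is the weighted
   mean of past diet values plus a constant trophic shift. Validation
   regresses measured on predicted values and reports RMSE.

Carbon-weighted mixing utilities reconstruct composite streams (diet from
grass + maize; whole milk back-calculated from lactose, casein and milk
fat) and compute the switch shift ε = δ_a − δ_b.

A synthetic-study generator (`isoturn.simulate`) reproduces the full study
design — 8 animals, fluctuating equilibration input, step switch, delayed
attenuated outputs with per-stream analytical noise — so every stage is
testable against known ground truth.

## Worked example

Simulate an idealized diet-switch experiment for a feces-like stream
(true delay 20 h, pool half-life 9 h, analytical noise 0.12 ‰) and run the
full pipeline:

```python
import isoturn as it
from isoturn.kinetics import CompartmentModel, Pool
from isoturn.simulate import OutputStreamSpec, gen_switch_experiment
from isoturn.timeseries import StudyDataset

truth = OutputStreamSpec(
    "feces",
    CompartmentModel(0.0, 20.0, [Pool.from_half_life(2.64, 9.0)]),
    trophic_shift=-2.11,
    noise_sd=0.12,
)
ds = StudyDataset()
for s in gen_switch_experiment(truth, seed=42):
    ds.add(s)

result = it.fit_stream(ds, "feces", seed=42)
print(result["_fit"].summary())
```

```
Turnover model fit
  stream: feces   animals: 8   n_obs: 104
  pools: 1   structure: c:s a:s tau:s   delay (fixed): 19.4783 h
  converged: True
  SSR: 1.28391   resid SD: 0.1127 permil
  logLik: 80.9435   AIC: -153.8870   k: 4

  param             estimate          SE
  c                  -32.144      0.0138
  a1                  2.6497      0.0815
  tau1                12.897       0.658
  pool 1 t1/2: 8.94 h (95% CI 7.86-10.02)
```

AIC kept a single pool with all parameters shared across the eight
animals. The estimated half-life (8.94 h, CI 7.9–10.0) and refined delay
(19.5 h) recover the generating values (9 h, 20 h); the gross half-life,
28.4 h, approximates `delay + t½ = 29 h`; the switch shift ε = −2.65 ‰
matches the simulated input switch.

The same pipeline runs from the shell:

```
isoturn simulate --seed 7 --out study.csv
isoturn fit     --data study.csv --seed 7 --out run/
isoturn predict --data study.csv --model run/model_lactose.json \
                --stream lactose --out run/
```

`fit` writes `run/report.json` (partition, selected fit, half-life CIs,
gross half-life, shift per stream) and one fitted-model JSON per stream;
`predict` writes predicted values and a validation report (RMSE,
slope/intercept tests, prediction interval).

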