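# bioenergize

Consumption-rate estimation for free-ranging fish by bioenergetics
modelling, with wild activity measured by accelerometry telemetry.

How much does a wild predator eat?  Bioenergetics models answer this by
balancing the energy budget: daily consumption `C` must cover metabolism
and growth after accounting for digestive losses,

```
C = (AMR + G) / A        [J g⁻¹ day⁻¹]
```

where `AMR` is active metabolic rate, `G = (Gv/W)·Fj` the energy allocated
to somatic growth, and `A` the fraction of consumed energy retained after
egestion, excretion, and digestion.  The hard part is `AMR` — the cost of
activity is large and usually guessed.  This package implements three
alternatives, parameterised for juvenile yellowtail kingfish
(*Seriola lalandi*), and is aimed at fish ecologists and bioenergetics
modellers who want to compare them or rebuild the workflow for another
species:

* **accelerometry** — wild activity (RMS triaxial acceleration transmitted
  by implanted acoustic tags) is converted to metabolic rate through a
  swim-tunnel calibration `MR = s·e^{b·Act}`, split into day and night
  periods: `AMR = [s·e^{b·Act_day}·h_d + s·e^{b·Act_night}·h_n]·Oxy`;
* **morphometric** — routine swimming speed from body shape,
  `log₁₀Speed = Int + Lc·log₁₀SL + Ac·log₁₀AR`, converted through the
  calibrated `MR = r·e^{z·SS}`;
* **physiological** — a Wisconsin-style allometric standard metabolic rate
  with Q10 temperature dependence and a fixed activity multiplier,
  `R = R_a·W^{R_b}·e^{(ln Q10/10)·T}·AM`.

Around the core sit the supporting stages: mixed-model calibration fitting
with AICc form selection (`calibration`), filtering and diel summarisation
of acoustic detections (`field_processing`), a typed parameter registry
with the packaged kingfish table (`parameters`), Monte Carlo uncertainty
propagation and standardized-regression sensitivity analysis
(`uncertainty`), synthetic data generators (`synthetic`), and a pipeline +
thin CLI (`pipeline`, `cli`).

## Worked example

```python
from bioenergize import MODELS, load_registry, point_estimate, run_monte_carlo

registry = load_registry()          # packaged kingfish parameter table
for i, model in enumerate(MODELS):
    est = point_estimate(registry, model)
    res = run_monte_carlo(registry, model, n=10_000, seed=1 + i)
    print(model, round(est["consumption"], 1), round(res.median, 1),
          round(res.lognormal_sigma, 3))
```

prints

```
accel 148.6 149.2 0.313
morph 117.8 119.3 0.608
physio 174.0 177.9 0.788
```

i.e. per model: the deterministic consumption at the parameter means, the
median of 10,000 Monte Carlo draws, and the σ (SD of log draws) of the
log-normal fitted to the simulated distribution.  The physiological
estimate is highest and the morphometric lowest; the accelerometry model —
the only one informed by measured wild activity — lies in between and has
by far the narrowest uncertainty, even though it carries real
between-individual variation.  See `examples/` for one short script per
capability (calibration fitting, field filtering, sensitivity analysis,
the full pipeline) and `docs/methods.md` for the model assumptions,
parameter table, and known caveats — including why the arithmetic means of
the morphometric and physiological simulations are dominated by heavy
exponential tails while their medians are stable.

A thin CLI mirrors the library:

```
bioenergize evaluate --model accel
bioenergize simulate --model all --n 10000 --seed 42 --summary summary.json
bioenergize synth respirometry --seed 1 --out trials.csv
bioenergize calibrate --input trials.csv --predictor activity --form compare
bioenergize run --config run.yaml
```

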