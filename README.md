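# migscale

Scaling-law analysis and simulation of city-to-city migration.

Internal migration between cities is strongly shaped by city size. Writing
`X_i*` for the annual out-migration from city `i` and `P_i` for its
population, migration quantities follow allometric scaling laws

```
X = α · P^β
```

estimated by ordinary least squares after taking logarithms of both sides
(the reported intercept is ln α). The per-capita rate `α·P^(β−1)` falls
with city size when β < 1 (*sublinear*) and rises when β > 1
(*superlinear*). In US census data the probability of leaving a city is
sublinear (β ≈ 0.88): residents of the smallest metropolitan areas are
roughly twice as likely to migrate as residents of the largest. The
destination choice also scales with size, with an exponent that depends on
the *origin's* size — migrants tend to preserve city size, and the
destination exponent crosses 1 (a phase transition) for origins of a few
million inhabitants.

`migscale` packages this analysis as a reusable toolkit:

- **`powerlaw`** — log-log OLS fits of `X = αP^β`, per-capita rates, rate
  ratios and sublinear/superlinear classification.
- **`beta_curve`** — the randomized moving-window estimator of the
  size-dependent destination exponent β(P): cities are repeatedly
  partitioned into non-overlapping log-width population intervals with
  random widths and offsets; each interval contributes one destination
  fit, and exponents are averaged at every point of the population axis.
- **`models`** — four flux models behind one prediction contract: the
  two-step stochastic *scaling* simulator (decide whether to migrate, then
  pick a destination, both by city size; countryside and international
  channels included), the *gravity* model `F_ij = a·P_i·P_j / d_ij^b`, the
  parameter-free *radiation* model, and the hybrid *gravity-scaling*
  model `π′_ij = C·π_ij / d_ij`.
- **`evaluation`** — model comparison (MSE and maximum error over all
  ordered city pairs) and small-city bias diagnostics.
- **`synthetic`** — generators for Zipf-sized city systems and OD flow
  matrices under a known kernel, plus replicated parameter-recovery
  experiments, so every estimator is testable without any data download.
- **`params`** — the published US coefficient bundle (385 metropolitan
  areas) shipped as packaged YAML.
- **`cli`** — a `migscale` command with `synth`, `fit`, `beta-curve`,
  `simulate`, `gravity-fit`, `radiation` and `evaluate` subcommands; every
  output carries a JSON provenance sidecar.

## Worked example

Generate a 385-city synthetic system whose flows follow a known scaling
kernel, then recover the generating parameters:

```python
import migscale as ms

spec = ms.SynthSpec(n_cities=385, rng_seed=7, dest_beta=0.9)
system = ms.gen_city_system(spec)
flow = ms.gen_flows(system, spec)

fit = ms.fit_power_law(system.populations.astype(float), flow.outflows)
print(f"beta = {fit.beta_hat:.4f} +/- {fit.se_beta:.4f}, "
      f"ln(alpha) = {fit.log_alpha_hat:.4f}, adj R2 = {fit.adj_r2:.4f}")
print(f"regime: {ms.classify_regime(fit)}")
print(f"per-capita rate at P=5e4:  {ms.per_capita_rate(fit, 50_000):.4f}")
print(f"per-capita rate at P=2e7:  {ms.per_capita_rate(fit, 20_000_000):.4f}")

curve = ms.build_beta_curve(flow, system, n_partitions=200, rng=3)
print(f"destination exponent near P=1e6: {ms.beta_at(curve, 1e6):.3f}")

gp = ms.fit_gravity(system, flow)
print(f"gravity fit: a = {gp.a:.3e}, b = {gp.b:.3f}")
```

prints

```
beta = 0.8829 +/- 0.0008, ln(alpha) = -1.7864, adj R2 = 0.9997
regime: sublinear
per-capita rate at P=5e4:  0.0472
per-capita rate at P=2e7:  0.0234
destination exponent near P=1e6: 0.901
gravity fit: a = 2.587e-10, b = 0.021
```

The out-migration fit recovers the generating exponent (0.8829) and
intercept, and classifies the relation as sublinear: the smallest cities
lose ~4.7% of their residents a year, the largest ~2.3%. The moving-window
curve recovers the flat destination exponent 0.9. The gravity fit returns
a distance exponent near zero — correctly so, because this synthetic
kernel ignores distance entirely; on gravity-generated flows the same
fitter recovers (a, b) to optimizer precision.

The same pipeline runs from the shell:

```sh
migscale synth --n 385 --seed 7 --out-cities cities.csv --out-flows flows.csv
migscale fit --cities cities.csv --flows flows.csv --out fits.csv
migscale beta-curve --cities cities.csv --flows flows.csv --partitions 1000 --seed 3 --out curve.csv
migscale simulate --model gravity-scaling --cities cities.csv --reps 100 --fraction 0.2 --seed 11 --out sim.csv
```

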