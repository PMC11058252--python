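# colim

Analysis toolkit for **light × nitrogen colimitation of microalgal
growth** measured in microhabitat gradient arrays.

Microfluidic hydrogel devices expose an R×C grid of nanoliter culture
chambers to a steady diffusive nitrogen gradient across rows (set by a
source and a sink perfusion channel) and a light-intensity ramp across
columns, so a single 8×8 array yields 64 distinct (PAR, [N])
combinations. `colim` covers the full analysis path for such
experiments:

1. **simulate** replicated array experiments (fluorescence time series
   with configurable seeding, noise and growth model) when raw data are
   needed for validation or power analysis;
2. **extract** the per-habitat maximum specific growth rate µ (day⁻¹)
   from each fluorescence curve by a sliding-window rule;
3. **fit** the multiplicative Monod colimitation model by weighted
   bootstrap nonlinear least squares, with model comparison against
   rival formulations;
4. **predict** growth rates over arbitrary light × nitrogen conditions.

## The model

Growth response to each resource alone is Monod; colimitation is
modelled as the product of the two saturating factors:

```
µ(L, N) = µmax · (L + L₀)/(K_L + L + L₀) · (N + N₀)/(K_N + N + N₀)
```

- `µmax` — maximum specific growth rate (day⁻¹)
- `K_L`, `K_N` — half-saturation constants (µmol·m⁻²·s⁻¹, µM)
- `L₀` — light-equivalent storage: acetate in the medium supports
  residual growth in the dark
- `N₀` — stored intracellular nitrogen (0 for starved cells)

The package also implements the generalized product over any number of
non-substitutable factors, a reduced multiplicative form (µ₀, K_L, K_N
free; storages zero), and a law-of-minimum (Liebig) alternative
µmax·min(f_L, f_N), so the multiplicative hypothesis can be tested
against its competitors on equal footing.

## Worked example

Simulate a noise-free 8×8 dual-gradient experiment (3 replicates,
samples every 4 h for 7 days) from known parameters, extract rates, and
fit the model — the free parameters come back exactly:

```python
import colim
from colim.synthetic_data import (SimulationConfig, NoiseConfig,
                                  SeedingConfig, simulate_array)

truth = colim.MonodParams(mu_max=2.4, L0=50.8, K_L=57.2, N0=0.0, K_N=2.8)
cfg = SimulationConfig(
    params=truth,
    noise=NoiseConfig(intensity_cv=0.0, background_level=100.0, background_sd=0.0),
    seeding=SeedingConfig(p_empty=0.0),
    seed=1,
)
series = simulate_array(cfg)                      # 192 habitat time series
matrix = colim.build_matrix(series, cfg.env, background=100.0)
fit = colim.nls_fit(matrix)                       # µmax fixed 2.4, N0 fixed 0
print({k: round(v, 4) for k, v in fit.free_values.items()})
```

prints

```
{'K_L': 57.2, 'K_N': 2.8, 'L0': 50.8}
```

i.e. the half-saturation constants of light and nitrogen and the
acetate storage term are recovered from the simulated fluorescence
curves alone. With measurement noise, `colim.bootstrap_fit` resamples
replicates per condition with weight 1/se² and refits B = 1000 times;
the parameter estimate is the bootstrap mean and its uncertainty the
bootstrap sd.

The same pipeline is available from the shell:

```bash
colim simulate --seed 1 --out run/sim
colim extract --timeseries run/sim/timeseries.csv --env run/sim/environment.csv --out run/ext
colim fit --matrix run/ext/growth_rates.csv --env run/sim/environment.csv -B 1000 --seed 1 --out run/fit.json
colim predict --report run/fit.json --out run/map.csv
```

`colim compare` reports mean SSE, R² and AICc for the multiplicative,
reduced and law-of-minimum forms over a shared bootstrap stream.

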