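# esnmort

Reservoir-computing estimates of how temperature drives monthly all-cause
mortality, and what that implies in warmer-world climate storylines.

The package is aimed at climate-impact and environmental-epidemiology work
of the following shape: gridded monthly-maximum 2 m temperature fields over
Europe (1° × 1°, 10°W–40°E × 30°N–65°N) are the inputs; the monthly
all-cause mortality rate of Germany (deaths per 100,000 inhabitants) is the
target; the question is how that rate shifts when the same weather is
replayed in a +2 K or +4 K world (storyline simulations).  Because a
monthly series gives very few training samples, the regression is an echo
state network (ESN): a large random recurrent reservoir that is never
trained, with a closed-form ridge readout as the only fitted part.

## Model

With input vector $u_n$ (the flattened, normalized temperature field of
month $n$) and reservoir state $x_n$, the leaky-integrator update and the
readout are

$$x_n = (1-\alpha)\,x_{n-1} + \alpha \tanh\!\big(W_\mathrm{in}[1;u_n] + W x_{n-1}\big),
\qquad y_n = W_\mathrm{out}[1;u_n;x_n],$$

where $W_\mathrm{in}$ is uniform on $[-0.5, 0.5]$, $W$ is uniform with a
fraction $1-c$ of entries zeroed and rescaled to spectral radius $r_s$, and
$W_\mathrm{out}$ solves a ridge regression of the mortality rate on
$[1;u_n;x_n]$ over the training months.  Defaults follow the study
configuration: reservoir size 9000, $\alpha=0.5$, $r_s=1.25$, $c=0.5$,
ridge penalty $\lambda=10^{-8}$.  Temperatures are normalized so that
$[-13\,°C, 47\,°C]$ maps to $[0,1]$; monthly population is interpolated
linearly from annual values anchored at mid-year.  An ensemble of 25
independently initialized networks quantifies the initialization
uncertainty; training uses Jan 2015–May 2019 and testing Jun–Dec 2019
(everything before 2020, to exclude pandemic excess mortality).

A seeded synthetic generator produces storyline-like temperature stacks
(seasonal cycle, coherent monthly anomalies, spatially correlated noise,
localized summer heat waves, scenario offsets with amplified extremes) and
a mortality series from a known hinge-shaped temperature response, so the
whole pipeline runs and is testable without any data download.

## Worked example

A scaled-down synthetic study (20 × 15 grid, 500-node reservoir, 10
members) from the library API:

```python
from esnmort import (ESNConfig, ExperimentPlan, SyntheticClimateSpec,
                     SyntheticResponseSpec, rate_to_absolute_deaths,
                     run_synthetic_experiment)

climate = SyntheticClimateSpec(lon_range=(0, 19), lat_range=(42, 56), seed=1003)
response = SyntheticResponseSpec(seed=2003)
plan = ExperimentPlan(ensemble_size=10, base_seed=93)
result = run_synthetic_experiment(climate, response,
                                  ESNConfig(reservoir_size=500), plan)
err = result.test_error
print(f"test RMS: {err.rms:.2f} per 100,000 ({err.rms_relative:.1f}% of the mean rate)")
for label, comp in result.comparisons.items():
    extra = rate_to_absolute_deaths(comp.summer_mean_diff, 80e6)
    print(f"{label}: summer {comp.summer_mean_diff:+.2f}, "
          f"winter {comp.winter_mean_diff:+.2f} per 100,000/month "
          f"(~{extra:+.0f} deaths/month in summer)")
```

prints

```
test RMS: 3.32 per 100,000 (3.8% of the mean rate)
plus2K: summer +2.10, winter -1.77 per 100,000/month (~+1678 deaths/month in summer)
plus4K: summer +3.52, winter -2.85 per 100,000/month (~+2819 deaths/month in summer)
```

The test RMS is the misfit of the ensemble-mean prediction over the seven
held-out months; the scenario lines are the mean differences between the
warmer-world ensemble predictions and the synthetic observations, averaged
over summer (Jun–Aug) and winter (Dec–Feb) months: warming raises summer
mortality through the heat response and lowers winter mortality through
the cold response, and a rate difference times population / 100,000
converts to absolute monthly deaths.

The same pipeline runs from the shell on files:

```sh
esnmort --config config.yaml simulate            # synthetic netCDFs + mortality CSV
esnmort --config config.yaml train-eval          # ensemble training + test RMS
esnmort --config config.yaml predict-scenarios   # +2K/+4K comparison bundle
esnmort --config config.yaml report              # PNG time-series plots
```

`simulate --check` and `train-eval --check` re-run the stage and verify
that the artifacts are digest-identical, so every output is reproducible
from config + seed alone.  For real inputs, point `temperature_paths` and
`mortality_path` at netCDF stacks (dims `time, lat, lon`, variable
`t2m_monthlymax`) and the deaths/population tables documented in
`esnmort.preprocess.load_mortality`.

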