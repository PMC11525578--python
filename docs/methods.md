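# Methods

## The regression problem

Monthly all-cause mortality in Germany is strongly seasonal (winter peak)
with a superimposed heat excess in hot summer months and a cold/respiratory
excess in cold winters.  The package links a short monthly series of such
rates (deaths per 100,000 inhabitants per month) to gridded
monthly-maximum 2 m temperature fields over a European box, then replays
warmer-world storyline fields through the trained map to project the rate
under +2 K / +4 K climates.  Five years of monthly data means about 50
training samples against ~2000 input cells, which rules out any trained
deep architecture; the echo state network is the standard
reservoir-computing answer: all recurrent structure is random and fixed,
and only a linear readout is estimated, in closed form.

## Network

State update and output:

    x_n = (1 - alpha) x_{n-1} + alpha tanh(W_in [1; u_n] + W x_{n-1})
    y_n = W_out [1; u_n; x_n]

* `W_in` (N × (1+K)) uniform on [-0.5, 0.5].
* `W` (N × N) uniform on [-0.5, 0.5]; each entry independently zeroed with
  probability 1 − c (Bernoulli thinning, matching the nominal connectivity
  in expectation with a single pass of randomness), then rescaled so the
  spectral radius is exactly r_s.  How r_s enters is not dictated by the
  update equation itself; rescaling after sparsification is the standard
  reading in the reservoir-computing practitioners' literature and is what
  we implement.  With c = 0 the matrix is identically zero and rescaling
  is skipped with a warning.
* Defaults: N = 9000, alpha = 0.5, r_s = 1.25, c = 0.5, lambda = 1e-8 —
  the study configuration.  Note r_s > 1 violates the classical sufficient
  condition for the echo-state property; the fading-memory test is
  therefore asserted at r_s = 0.8 (and with alpha = 1, where the
  contraction is fastest; leakage < 1 slows the same geometric
  convergence), not at the working radius.

The readout is ridge regression of the (unscaled) rate on d_t = [1; u_t;
x_t] over training steps beyond the washout.  Since the feature count
1 + K + N vastly exceeds the sample count T, the solver uses whichever
normal-equation formulation has the smaller linear system: the feature
space form (D'D + lambda I)^-1 D'y when features <= samples, else the
sample-space (dual) form D'(DD' + lambda I)^-1 y, which is a T × T solve.
The two agree exactly for lambda > 0; at lambda = 1e-8 the fit
interpolates the training months.  Targets are used unscaled (rates
~80–110); only the inputs are normalized.

Numerical details: spectral radii come from dense eigenvalues up to
N = 2500 and from ARPACK (largest-magnitude eigenvalue, tol 1e-10) above;
an all-identical design matrix triggers a warning and a pseudo-inverse
fallback; a degenerate (zero) pre-scaling spectral radius is an error.

## Protocol

* Training Jan 2015 – May 2019 (53 months), test Jun – Dec 2019 (7
  months); everything ends before 2020 to exclude pandemic excess
  mortality.  The reservoir runs once over the contiguous train+test
  stream from x_0 = 0; the readout is fitted on training months beyond the
  washout (default 6 months — the source description never mentions a
  transient, but some suppression is standard practice with so short a
  series), and test predictions reuse the states of the same run, so the
  test-time state continues from the end of training.
* Ensemble: 25 members by default, differing only in the initialization
  seed (base_seed + member index); training data are never resampled.
  Member results are independent of execution order.  The per-month mean
  and population standard deviation across members are the prediction and
  its robustness measure.
* Scenario prediction: warmer-world inputs are not temporally contiguous
  with the training stream, so each member's reservoir is restarted from
  zero.  Where scenario inputs exist before the evaluation span (the
  synthetic suite generates 2015–2019 for every offset), the reservoir is
  driven through the full stream and evaluated on 2017–2019 — a 24-month
  spin-up.  This matters because at r_s = 1.25 the dynamics are not
  contractive and a 6-month spin-up leaves states unlike anything the
  readout was fitted on.  Real storyline files that begin in 2017 fall
  back to an in-span washout of 6 months.
* Differences are scenario ensemble mean minus the observed (reference
  period) rates, aligned by calendar month; summer = Jun–Aug as in the
  source analysis, winter = Dec–Feb as our symmetric reporting choice.
  `rate_to_absolute_deaths` converts a per-100,000 difference to monthly
  deaths via the population.

## Synthetic data

The generator emulates the statistical features the method needs from
storyline output, not the climate model itself:

* Climatology: a north–south gradient (38 °C at 30°N falling 0.6 K/deg)
  plus a seasonal cosine peaking in July (amplitude 12 K).  These are
  monthly *maxima*, hence warmer than monthly means.
* A domain-coherent monthly anomaly, N(0, 1.8 K).  Monthly temperature
  anomalies over a continental box are synoptically coherent, and this
  hot-summer/mild-winter variability is exactly what makes a
  temperature–mortality response identifiable from five years of data;
  without it the response covariates are collinear with the seasonal
  cycle.
* Cell-scale correlated noise: white noise smoothed with a Gaussian
  kernel (correlation length 4°, a free knob — an 8° variant was examined
  and rejected as it merely inflates the coherent variability), rescaled
  to 1.5 K per-cell SD.
* Heat waves: Poisson(2) events per summer, Gaussian footprints with
  sigma uniform on [1.5°, 3°] (localized, a few hundred km), central
  amplitude 6 K × U(0.5, 1.5).  A localized event raises the
  Germany-box mean by ~1–2.5 K, like a record summer month; wide
  footprints were rejected because they produced unphysical domain-mean
  extremes.
* Scenarios: the offset w ∈ {0, 2, 4} K is added uniformly after all
  stochastic draws, so equal seeds give fields that differ by exactly w
  when extreme amplification is 1; heat-wave amplitudes additionally scale
  by 1 + (A − 1)·w/4 (default A = 1.5), so local exceedances exceed the
  mean offset, as in storyline output.

Ground-truth mortality: with T_m the unweighted mean of the monthly field
over a Germany-covering box (5–15°E, 47–55°N),

    rate_m = 90 + 8 cos(2 pi (month-1)/12)
             + 1.2 max(0, T_m - 34)          # heat excess
             + 1.0 max(0, 16 - T_m)          # cold/respiratory excess
             + N(0, 1.0)

in deaths per 100,000 per month, with population 80 million (interpolated
mid-year like the real tables; deaths are kept as expected counts so the
rate/deaths/population identity is exact).  The baseline and seasonal
amplitude reproduce the scale of the real series (~82–103); the heat
coefficient is calibrated so that the ground-truth +4 K summer increase is
≈ 4.6 per 100,000/month, the magnitude reported for the real +4 K
storyline.  With the noise off, ordinary least squares on the true
covariates recovers all four coefficients to < 1e-6 relative error.

What the generator does **not** emulate: atmospheric dynamics and nudging,
spatially structured warming patterns, humidity/wet-bulb inputs (the
input vector accepts any flattened field, so such experiments are a
preprocessing change only), demographic drift, influenza epidemics, and
reporting artifacts.  Passing tests on synthetic data therefore show that
the pipeline recovers a known low-dimensional response embedded in
realistic-looking fields — not that the real-data headline numbers are
reproduced, which would require the archived storyline fields and the
official mortality tables.

## Scaled-down recovery, honestly

The development-scale study (20 × 15 grid, 500-node reservoir, 10
members, the ground truth above) recovers the response *qualitatively*
with high reliability: across 20 seeded repetitions the +4 K comparison
shows a positive summer shift and a negative winter shift in ~95% of runs
each.  Quantitatively, the ensemble-mean test RMS is ~2.4–3.4 per 100,000
(~3% of the mean rate), which is dominated by structural bias of the
interpolating readout, not by ensemble spread (~1.2 per month, averaged
down by the members) or by the observation noise (1.0).  An oracle-tuned
RBF kernel ridge on the identical training sets reaches ~1.6, so the
information is present; but regularizing the ESN readout to that level
(leave-one-out-selected lambda, typically ~0.1) suppresses exactly the
out-of-distribution response to the +4 K shift that the scenario
comparison measures, collapsing the summer-shift sign rate to ~60%.  The
in-distribution accuracy and the out-of-distribution responsiveness are
coupled through the ridge penalty with opposite signs.  We keep the
study's lambda = 1e-8: the scenario response is the scientific point, and
a ~3% test misfit is the honest price at 47 effective training months.
The corresponding acceptance check (test RMS within three noise SDs *and*
both shift signs, jointly in ≥ 95% of repetitions) sits beyond this
ceiling at roughly 55–60% and is expected to fail; it is kept unweakened
as a statement of the gap.

## Limitations

* The spectral radius 1.25 leaves the echo-state property unproven; the
  package verifies fading memory only at sub-unit radii.
* Scenario projections are extrapolations: +4 K inputs exceed the
  training range (normalized values above 1 are deliberately not
  clipped), and the network's response there is shaped by the readout's
  inductive bias, not by data.
* Whether the "monthly maximum" of the source fields is a max of hourly
  values or of daily maxima is immaterial — max-reduction commutes — and
  the hourly→monthly reduction uses calendar months in UTC.
* National aggregation only: per-state deaths and populations are summed
  before the rate is formed; no age stratification or cause-of-death
  breakdown.
* No forecasting mode: the network is used strictly as a response map to
  new inputs, never autoregressively.
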