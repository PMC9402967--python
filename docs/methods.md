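# Methods

`aircast` implements a decomposition-ensemble forecasting method for daily
air-pollutant concentration panels, plus the downstream conversion of
forecast annual means into avoidable premature deaths. This note records
the models, the defaults and why they were chosen, the numerical details,
and the known limitations.

## The forecasting model

The target pollutant series x(t) is split into intrinsic mode functions
(IMFs) and a residue by complete ensemble empirical mode decomposition
with adaptive noise (CEEMDAN), x(t) = Σᵢ cᵢ(t) + r(t). Each component is
forecast one step ahead by its own small convolutional-recurrent network
(CNN-LSTM), and the pollutant forecast is the exact sum of the component
forecasts. A particle swarm optimiser (PSO) selects one shared pair of
hyperparameters per target series — the look-back window n ∈ [1, 20] days
and the LSTM hidden size ∈ [1, 100] — by minimising the validation RMSE of
the reconstructed forecast.

Rationale: decomposition turns a non-stationary, noisy series into a set
of components that are individually much easier to extrapolate; summing
per-component forecasts recovers the original scale exactly because the
residue is defined by subtraction.

### Empirical mode decomposition

* **Sifting.** A candidate IMF is refined by h ← h − (upper + lower)/2,
  where the envelopes are cubic splines through the local maxima / minima.
  Plateaus contribute one extremum at their midpoint index
  (deterministic). Boundaries are handled by mirroring the two extrema
  nearest each endpoint about that endpoint before the spline fit — the
  standard remedy for end swings.
* **Stopping.** Sifting stops when the Cauchy-like criterion
  Σ mean² / Σ h² < `sd_threshold` (default 0.2) **and** the IMF condition
  |#extrema − #zero-crossings| ≤ 1 both hold, or after
  `max_sift_iterations` (default 50). Requiring the IMF condition as part
  of the stop rule is what makes the decomposition-completeness property
  (every returned IMF is a valid IMF) hold on rough signals; the SD
  criterion alone does not guarantee it.
* **Termination.** Mode extraction ends when the running residue has fewer
  than two maxima or two minima (monotone trend), so a constant input
  yields zero IMFs and residue = input.

### Ensemble variants

* **EEMD** averages full EMD decompositions of white-noise-perturbed
  copies, aligned by component index. Reconstruction is only approximate
  in general; with paired ± noise the perturbations cancel in the mean and
  reconstruction is tight in practice.
* **CEEMDAN** (the pipeline default) extracts IMF_k as the ensemble mean
  of the *first* EMD mode of (running residue + ε_k · E_k(noise)), where
  E_k is the k-th EMD mode of each pre-decomposed noise realisation. The
  final residue is literally the input minus the extracted IMFs, so
  reconstruction is exact to machine precision for any seed.
  * Noise is drawn once per decomposition and used in ± pairs
    (`paired_noise`, default on; requires an even `ensemble_size`).
  * ε_k = `noise_scale` × std of the current residue (the "adaptive"
    schedule); a fixed ε referenced to the input's std is available via
    `adaptive_noise=False`.
  * Ensemble means of IMFs are not themselves valid IMFs (averaging leaves
    small ripples), so each ensemble-mean mode is post-sifted before being
    accepted; the remainder stays in the running residue and exactness is
    unaffected. This mirrors the refinement used by improved-CEEMDAN
    variants.
  * Defaults: `ensemble_size` 100, `noise_scale` 0.2 — conventional values
    from the ensemble-EMD literature; both configurable.

### The component forecaster

Architecture (fixed; only n and the cell count are tuned):
1-D valid convolution (16 filters, kernel 2, ReLU) → non-overlapping max
pooling (size 2 when the convolution output has ≥ 4 steps, else 1) → LSTM
→ linear head. The LSTM uses standard gates with biases plus a diagonal
peephole from the fresh cell state into the output gate:

    i = σ(W_hi h + W_xi x + b_i),  f = σ(W_hf h + W_xf x + b_f)
    c' = f⊙c + i⊙tanh(W_xc x + W_hc h + b_c)
    o = σ(W_xo x + W_ho h + w_co⊙c' + b_o),  h' = o⊙tanh(c')

The network is plain NumPy with hand-derived gradients (verified against
central differences to ~1e−6 in the tests) and Adam (β₁ 0.9, β₂ 0.999).
Training defaults: 60 epochs, batch 32, learning rate 1e−3, MSE loss,
Glorot-uniform init with the forget-gate bias at 1. All randomness (init,
shuffling) flows from one seeded generator, so seeded training is
bit-reproducible. When the window is shorter than the kernel the kernel is
shrunk to the window so one-day windows remain valid.

### Windowing, scaling and splitting

Each sample is X[t] = rows t−n … t−1 of [component ∥ covariates] with
target y[t] = component[t]; channels are the component itself plus the
five *raw* (undecomposed) covariate pollutant series. Channels are min-max
scaled to [0, 1] with parameters fitted on the **training rows only**;
predictions are inverse-scaled per component before summing.

The split is chronological: calendar years 2016–2020 for
training+validation (validation = last 20% of those rows, rounded down,
never shuffled) and 2021 as the held-out test year.

### Decomposition window and look-ahead

By default the target series is decomposed **once over its full span**
(`decomposition_window="full"`), matching the source methodology in which
the decomposition figure spans all six years. This is a deliberate,
documented leak: the component values inside the test year were computed
with knowledge of the whole series, which flatters decomposition-based
models. The strictly causal alternative (`"expanding"`) re-decomposes the
history before every forecast origin and is exercised in the tests on
small panels; it costs one decomposition per test day. The no-look-ahead
audit (perturbing future values must not change earlier predictions) is
asserted on the decomposition-free path and on the expanding mode, where
the property genuinely holds.

### Hyperparameter search

PSO with the canonical Kennedy–Eberhart update (inertia 0.8, cognitive =
social = 2.0, velocity clamp at half the box range, zero initial
velocities). The published update formula carries a negated cognitive term
with the two attractors swapped; it diverges from every standard PSO
reference, so the canonical form is the default and the literal form is
kept behind `use_printed_update=True` for comparison. Positions are
continuous internally and rounded to integers only at fitness evaluation
and in the final report, preserving swarm dynamics on the integer lattice;
integer configurations are cached so the swarm never retrains a pair it
has already scored.

Search fitness = validation RMSE of the reconstructed forecast with
component models trained at a reduced budget: 15 epochs on the most recent
192 training windows with batch 96. The final model is retrained at the
full budget. The reduced-fitness settings are a desk-scale choice; they
rank (n, cells) candidates adequately because the per-component learning
problems are close to linear at this window size.

## Evaluation

RMSE and MAE as usually defined. Two R² forms are reported: the
explained-variance ratio Σ(f−ȳ)²/Σ(y−ȳ)² used by the source methodology,
and the conventional 1 − SSE/SST. They coincide when predictions are an
orthogonal projection of y (OLS fitted values) but not in general; the
conventional form is used for ranking and both are printed. Comparison
tables report pairwise percent reductions 100·(before−after)/before
rounded to two decimals, plus R² differences. The persistence forecast
ŷ_t = y_{t−1} is the built-in skill floor.

## Synthetic panels

The six-city monitoring data behind the methodology are not deposited, so
tests and experiments run on seeded synthetic panels emulating their
documented structure:

    c(t) = max(0, base·(1 + trend·t/365.25)
                 + amplitude·cos(2π(doy − peak)/365.25) + e(t))

with peak day-of-year 15 for the five winter-peaking channels (PM2.5,
PM10, SO2, NO2, CO) and 196 for O3, per-channel AR(1) noise e(t) driven by
innovations correlated across channels through the eigen factor of a
configurable correlation matrix (rejected with a diagnostic if not
positive semidefinite).

Default levels (base, seasonal amplitude, annual trend, AR coefficient,
noise sd) are set to resemble heavily polluted northern-Chinese cities:
e.g. PM2.5 base 55 μg/m³, amplitude 30, trend −6%/yr, AR 0.6, noise sd
12 μg/m³; CO in mg/m³; O3 with a slight positive trend. The correlation
defaults (+0.5 among the winter-peaking five, −0.2 with O3) are
placeholders for the qualitative statement that the six pollutants co-move
— nothing in the source quantifies them. What the generator does **not**
emulate: meteorological drivers, sandstorm spikes, heteroscedastic winter
noise, holiday effects, or measurement gaps. Passing tests therefore
demonstrate the machinery and its relative ordering on well-behaved
seasonal AR data, not absolute real-data accuracy.

## Health burden

Reference limits (WHO 2021 guideline; China national first/second class)
and linear excess-risk coefficients (percent mortality increase per
10 μg/m³ exceedance, per 1 mg/m³ for CO) are built in as registries. The
linear form is used because the coefficients are published directly in
that form; a log-linear relative-risk option exists for sensitivity
analysis (identical at one unit step by construction). Avoidable deaths =
baseline annual deaths × excess%/100, reported in 10⁴-person units with
the CI propagated linearly from the coefficient's 95% CI. Baseline
mortality is a required user input: it is demographic data the
concentration series cannot supply, so absolute death counts are only as
good as that input. Estimates are exactly zero when the annual mean meets
the reference, and monotone in both exceedance and standard strictness.

## Problem sizes used in the shipped experiments

The acceptance experiment uses the default six-year panel (2192 days), a
PSO budget of 10 particles × 10 iterations, 15 training epochs, CEEMDAN
ensemble 100 for the pipeline and ensemble 8 on the 256-point
completeness fixtures. These sizes were chosen so a full run completes on
a single CPU core in minutes while leaving the qualitative ordering
(hybrid < no-decomposition < persistence in test RMSE) stable across
seeds.

## Known limitations

* The full-span decomposition default leaks future information into the
  component values (see above); use `expanding` mode for honest causal
  evaluation, at substantial cost.
* One-step-ahead only; no multi-day horizons.
* The exploratory `all_imf_channels` mode (feeding covariate IMFs rather
  than raw covariates) is provided but not validated.
* EEMD component alignment by index can mix modes when ensemble members
  produce different mode counts; CEEMDAN is the recommended variant.
* The health module is not age- or cause-stratified and uses a single
  national-style exposure-response coefficient per pollutant.
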