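# Methods

This note documents the statistical model and procedure behind `fishstatus`,
the choices made where the design was genuinely open, and what the synthetic
panels do and do not establish about behaviour on real assessment data.

## Quantities and targets

For each stock we track two dimensionless status ratios: biomass relative to
the biomass target, b = B/B_target, and exploitation rate relative to its
target, u = U/U_MSY. A ratio of 1 marks the target line; b ≥ 1 and u ≤ 1
together define the "recovered" (green Kobe) state. Boundary values count as
within target: the choice is measure-zero on continuous data but must be
fixed for reproducibility, and the inclusive direction is applied uniformly
(per-stock Kobe classification, per-member recovery verdicts, and the
proportion-within-target series). Recovery verdicts additionally allow a
1e-9 numerical slack at the line so that data sitting exactly on a target is
not reclassified by floating-point jitter.

Two biomass targets are supported:

- `assessment_bmsy` — the B_MSY estimated by the stock assessment. A
  pre-divided B/B_MSY series, when present, takes precedence over B divided
  by the reported reference point (the assessment-reported ratio is treated
  as authoritative; disagreement beyond 5% is logged).
- `half_max_biomass` — half the maximum of the *observed* biomass series
  within the data window (maximum over non-missing years only). This is an
  empirical precautionary target, not an estimate of unfished biomass; no
  production model is fitted. Switching targets rescales each stock's b
  series by one positive constant and leaves u untouched.

Exploitation ratios use a pre-divided U/U_MSY series when available, else
U divided by the reported U_MSY.

## The ten-member ensemble

Per year and per quantity, five averaging methods are applied under each
target definition (5 × 2 = 10 members):

- **Unweighted mean** and **weighted means** with time-invariant weights:
  each stock's time-mean observed biomass (biomass-weighted) or time-mean
  catch (catch-weighted). Time-invariant weights are deliberate: annual
  weights would conflate trends in the weights with trends in status. The
  weighted mean is x̄_w = Σwᵢxᵢ/Σwᵢ with SE = sqrt(Σwᵢ²(xᵢ−x̄_w)²)/Σwᵢ.
- **Median**, with the large-sample normal-theory SE 1.2533 × SE of the
  mean; a closed form avoids a bootstrap dependency.
- **Hierarchical state-space smoother** (below).

Averaging is on the arithmetic ratio scale, since the recovery criterion is
stated on that scale; a geometric-mean variant exists
(`method="geometric_mean"`) but is excluded from the ensemble. Years with
fewer than `min_stocks_per_year` (default 20) reporting stocks are masked in
every member. The last reporting year is the latest year in which at least
50% of the filtered stocks report — the operational meaning of "the last
year with sufficient data"; the endpoint comparison defaults to starting in
1980. The ensemble summary per year is the unweighted mean across available
members with a 95% interval of mean ± 1.96 × SD (ddof = 1) across members;
with only ~10 members a percentile interval would be unstable. Fewer than
two members in a year leaves the interval undefined.

## Hierarchical state-space smoother

Fitted on log ratios (ratios are positive and right-skewed; a random walk is
scale-free on logs):

    x_t = x_{t-1} + eta_t,          eta_t ~ N(0, sigma_proc^2)
    y_{s,t} = x_t + a_s + eps_{s,t},  a_s ~ N(0, sigma_stock^2),
                                      eps_{s,t} ~ N(0, sigma_obs^2)

with a diffuse initial-level prior x_1 ~ N(0, 1e6). Everything latent is
Gaussian, so the marginal likelihood of (sigma_proc, sigma_stock, sigma_obs)
is exact: stock offsets integrate out within each stock (conditional
covariance sigma_obs² I + sigma_stock² J, inverted as a rank-one update),
and the trajectory integrates out via the Gaussian evidence identity. The
trajectory is parameterised by its initial level and yearly increments,
whose prior covariance is diagonal — this keeps all determinants and solves
well conditioned under the diffuse prior (the naive dense-covariance
evaluation loses ~8 digits there), and the quadratic form is evaluated in
the residual form y'R⁻¹(y − x̂) to avoid cancellation. One evaluation costs
O(T³ + Σ_s n_s²) and yields the smoothing posterior N(E[x_t|y], Var[x_t|y])
for every year in the window, including years with no observations
(interpolated through the random walk).

Variances are estimated by L-BFGS-B on log-variances (bounds e^-23..e^8,
likelihood tolerance 1e-8) from four deterministic starts centred on the
empirical variance; the best optimum is kept, with a warning and a
diagnostic flag if no start converges or a variance sits at its lower bound
(as happens for degenerate constant input). Back-transformation to the
ratio scale uses the lognormal mean exp(m + v/2) with delta-method SE
exp(m + v/2)·sqrt(v). With a single stock the offset variance can be pinned
(`fix_stock_var=0`), reducing the model to the univariate
random-walk-plus-noise smoother exactly.

The model treats offsets as exchangeable and time-constant and shares one
observation variance across stocks; it is one defensible specification of a
"hierarchical state-space smoother", documented here as this package's own.

## Per-stock diagnostics

Trends are OLS slopes of each ratio on calendar year over the stock's **last
10 observed years** (not a fixed calendar window — assessments end in
different years), requiring at least 8 of the 10 (`min_trend_years`,
configurable). Trend direction is classified by the sign of the slope with
no significance filter; a p-value threshold exists behind a flag. The "up
to" headline percentages are maxima across the two target definitions.
Proportion-within-target series start in 1950 among stocks reporting each
year, subject to the same `min_stocks_per_year` rule; extrema report the
maximum proportion below/above target (earliest year on ties, ties
recorded) and the improvement to the final defined year in percentage
points (max minus final).

## Synthetic panels

The simulator is the package's test bed and default input. Each stock
follows Schaefer (logistic) surplus production, chosen because the targets
have closed forms (B_MSY = K/2, U_MSY = r/2) so truth recovery is checkable
exactly. Defaults define the study conditions: 200 stocks over 1950–2016;
K lognormal with log-mean ln(1e5) and log-SD 1.5 (spans several orders of
magnitude, as real panels do); r uniform on (0.1, 0.8); lognormal
observation error with log-SD 0.2 applied independently to biomass and
exploitation rate (catch reported exactly); 20% of stocks missing their
last 1–5 years. The default exploitation history ramps from 0.2 to
1.8 × U_MSY over the first 60% of years, then eases back to 0.9 × U_MSY —
an industrialisation-then-reform shape that puts the biomass low point a
couple of decades before the end of the series. Biomass is floored at
10⁻³ K with the run flagged; a stock that hits the floor has its parameters
redrawn up to 20 times before the simulation errors out.

What the generator does **not** emulate: age structure, process error in r
or K, time-varying productivity, assessment-model estimation error in the
reference points themselves (truth is reported with observation noise
only), and the empirical distribution of start years and series lengths,
for which no authoritative description was available — so passing tests
demonstrate correctness of the aggregation machinery under known dynamics,
not calibration of any real-world headline number. The empirical analysis
requires the RAM Legacy CSV export (`data/ram/README.md`).

## Numerical and scale choices

- Problem sizes in the test suite (e.g. 100 stocks × 40 years for the
  smoother's coverage check, 25–40 stocks for end-to-end runs) are chosen so
  the full suite runs in well under a minute while leaving estimator noise
  far smaller than the effects being asserted.
- All randomness flows through `numpy.random.default_rng` seeded from one
  configuration field; rerunning a pipeline with the same seed is
  byte-identical (CSV floats use a fixed `%.10g` format).
- CSV reads use round-trip float parsing so export → import is lossless.
- Ties in extrema years resolve to the earliest year; all-missing years
  propagate as missing, never as zero.
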