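# fishstatus

Ensemble assessment of global fish-stock status from stock-assessment time
series.

Whether the world's scientifically assessed fish stocks have, on average,
recovered to their management targets depends strongly on *how* one averages
across hundreds of heterogeneous stocks: trends vary wildly between stocks,
recent years are missing for many, and stock sizes and catches span orders of
magnitude. `fishstatus` makes that methodological sensitivity explicit. For a
panel of stocks with biomass (B), exploitation rate (U; the fraction of
biomass caught per year) and reference points, it computes an **ensemble of
ten global trajectories** of B/B<sub>MSY</sub> and U/U<sub>MSY</sub> — five
averaging methods crossed with two rebuilding targets — rather than
committing to a single diagnostic:

- **Averaging methods:** unweighted mean, biomass-weighted mean,
  catch-weighted mean, median, and a hierarchical state-space smoother
  (a latent random-walk global trajectory x<sub>t</sub> with stock-level
  offsets a<sub>s</sub>, fitted by exact marginal maximum likelihood to the
  panel of log ratios: y<sub>s,t</sub> = x<sub>t</sub> + a<sub>s</sub> +
  ε<sub>s,t</sub>).
- **Rebuilding targets:** the assessment-estimated B<sub>MSY</sub>, and the
  precautionary target of half the historically observed maximum biomass.

A stock (or the global average) is *within target* when B ≥ B<sub>target</sub>
and U ≤ U<sub>MSY</sub> — the green quadrant of the Kobe plot. The package
reports, per year and per member, estimates with standard errors; the
ensemble mean with a 95% interval across members; per-member recovery
verdicts at the endpoint year; per-stock Kobe quadrants, 10-year trend
slopes, and the proportion of stocks within targets since 1950.

A Schaefer surplus-production simulator
(B<sub>t+1</sub> = B<sub>t</sub> + rB<sub>t</sub>(1 − B<sub>t</sub>/K) −
C<sub>t</sub>, so B<sub>MSY</sub> = K/2 and U<sub>MSY</sub> = r/2 exactly)
generates synthetic panels with known truth, staggered coverage, lognormal
observation error and missing recent years, so the entire pipeline is
testable without any data download.

## Worked example

```sh
fishstatus run --simulate --seed 42 --out demo_run
fishstatus report demo_run
```

prints (abridged):

```
Endpoint year: 2016
Members supporting recovery (B at/above target and U at/below target): 0 of 10; refuting: 10; undetermined: 0.
Members whose 95% CI straddles the B=B_MSY line: 1; the U=U_MSY line: 0.

          method      target_kind  year     b  b_se     u  u_se verdict
 unweighted_mean  assessment_bmsy  2016 0.898 0.017 0.935 0.015  refute
  catch_weighted  assessment_bmsy  2016 0.951 0.031 0.909 0.020  refute
     state_space  assessment_bmsy  2016 0.867 0.015 0.918 0.014  refute
 unweighted_mean half_max_biomass  2016 0.734 0.015 0.935 0.015  refute
 ...

Up to 92.5% of stocks below the biomass target; up to 35.0% above the exploitation target.
```

Reading this: the simulated world (fish-down followed by partial rebuilding)
ends 2016 with every member's global-average biomass ratio below 1 — the
catch-weighted member is closest to target and the only one whose 95% CI
straddles the B = B<sub>MSY</sub> line. The half-max-target members sit
uniformly below their assessment-target counterparts (0.71–0.76 vs
0.87–0.95): assessment B<sub>MSY</sub> values are lower than half the
historical maximum, so they are easier to satisfy. The exploitation columns
are identical between target kinds, as they must be — only the biomass
denominator changes.

The same pipeline runs on real long-format exports (columns
`stock_id, series_id, year, value` plus a reference-point table) via
`fishstatus run --timeseries ts.csv --refpoints rp.csv`; series naming is
resolved through an editable alias map (see `fishstatus.ramio`), and
`--series-preference spawning_biomass` switches the biomass family.

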