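# ltsseff

Two-step cost-efficiency analysis for state long-term support service (LTSS)
panels.

**Step 1 — stochastic cost frontier.** A panel stochastic frontier for log
total cost with two output elasticities (institutional and home/community
participant counts), year dummies, and a composed error `eps = v + u`:
Gaussian noise `v` plus one-sided inefficiency `u_it = u_i * exp(-eta (t - T_i))`
with `u_i` truncated-normal (half-normal and a pooled exponential variant are
also available). The state-level marginal likelihood is closed-form (the
truncated-normal integrates out analytically) and is maximized over an
unconstrained parameterization with multi-start BFGS plus a damped-Newton
polish. Efficiency scores are the posterior mean `E[u_it | eps_i]`, reported
as `score = 100 * u_hat` with `ce = exp(-u_hat)`.

**Step 2 — policy regression.** Log scores are regressed on
HCBS/waiver/ICFMR shares, managed-care and certificate-of-need indicators,
and socioeconomic controls with state fixed effects, CR1 cluster-robust
standard errors, a Swamy–Arora random-effects alternative, and a Hausman
specification test. Coefficients are presented multiplicatively via
`exp(b)` / `1 - exp(b)` (truncated to two decimals).

A seeded synthetic-data module generates panels with known ground truth in
two modes: `bc92` (matches the frontier likelihood; used for parameter
recovery) and `covariate_driven` (inefficiency driven by covariates;
deliberately misspecified, used to exercise the full two-step procedure).
Panel ingestion applies the study's sample-construction rules (AZ excluded
entirely, VT truncated after 2005; CPI deflation to 2005 dollars).

## CLI

```sh
# seeded synthetic panel + ground truth
ltsseff simulate --seed 7 --out panel.csv --truth truth.json

# frontier fit and scores
ltsseff fit-frontier --panel panel.csv --dist tnormal --base-year 2007 \
    --out fit.json --scores scores.csv

# fixed-effects second stage with cluster-robust inference
ltsseff second-stage --scores scores.csv --panel panel.csv \
    --estimator fe --out table.json

# rankings, score table, quartile trends
ltsseff report --scores scores.csv --out report_dir/

# everything from one YAML config
ltsseff pipeline --config cfg.yaml
```

A pipeline config looks like:

```yaml
out_dir: run/
seed: 7
simulate: {n_states: 50, years: [1999, 2007]}
frontier: {dist: tnormal, base_year: 2007}
second_stage: {estimator: fe, cluster: state}
```

Use `panel: path/to/panel.csv` instead of `simulate:` to ingest real data,
plus optional `exclusions: default` and `deflate: {base_year: 2005}` blocks.

## Notes

- Scores are reported on a 0–100-ish scale (`100 * u_hat`) so magnitudes
  are comparable to published efficiency tables; raw `u_hat` and `ce`
  accompany every score.
- Under the decay model, within-state score variation is exactly the fitted
  time trend, so second-stage coefficients are identified only through
  covariate time trends and are attenuated relative to any
  covariate-driven generating process (see `tests/test_end_to_end.py`).
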