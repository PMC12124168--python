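# rrtsurvey

Simulation and Bayesian estimation for household surveys in which answers
about sensitive items are masked by an **unrelated-question randomizer**
(randomized response technique): a physical device routes each respondent to
the sensitive question with probability `p_s` (default 4 of 6 tokens) or to
an innocuous unrelated question otherwise, so only aggregate prevalence is
estimable.

The package provides:

- **`rrtsurvey.design` / `rrtsurvey.simulate`** — a seeded generator for
  stratified household surveys (default: 782 households over six
  municipality × urbanization strata) with covariate-driven latent behavior,
  the domino-style randomizer, and a strict truth/analysis file split (the
  latent question assignment never reaches analysis-facing files).
- **`rrtsurvey.prevalence`** — per-cell estimation of sensitive prevalence
  from masked binary responses: a method-of-moments inversion, a
  data-augmentation Gibbs sampler with conjugate Beta updates, and an exact
  grid-posterior oracle for verification; equal-tailed 95% credible
  intervals with rank-normalized split-chain rhat and ESS.
- **`rrtsurvey.quantity`** — masked proportional-odds (ordered logistic)
  regression of quantity categories on household covariates via
  MH-within-Gibbs, reported as odds ratios per 1 SD for standardized terms.
  At `p_s = 1` it collapses to a standard proportional-odds fit.
- **`rrtsurvey.glms`** — NB2 negative binomial regression for visit counts
  (incidence rate ratios) and logistic regression for household structure
  (odds ratios), both with Wald 95% intervals.
- **`rrtsurvey.pipeline` / CLI** — a config-driven, fully seeded
  generate → estimate → report pipeline with a SHA-256 artifact manifest;
  identical configs reproduce identical artifacts bit-for-bit.

## CLI

```sh
rrtsurvey all --config config.yaml            # generate + estimate + report
rrtsurvey generate --config config.yaml --seed 7 --workdir out/
```

Minimal `config.yaml`:

```yaml
seed: 1
workdir: out
design: default          # 782 households, 6 strata, 4/6 randomizer
params: default
mcmc: {n_burnin: 2000, n_samples: 2000, n_chains: 2}
quantity_models:
  - domain: "mammals_birds:consumption"
    covariates: [manaus, rural, peri_urban, multisited, dry]
```

Outputs in the workdir: `households.csv`, `responses.csv`,
`responses.truth.csv`, `prevalence_summary.csv`, `quantity_*.csv`,
`glm_*.csv`, `prevalence_table.csv` (percent scale, 72 layout cells),
`report.txt` ("21% [95% CI 7–34]"-style lines), and `manifest.json`.

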