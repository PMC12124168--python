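# Full-scale default run: 782 households, all prevalence cells, three GLMs,
# one quantity model. MCMC settings here are moderate; raise n_burnin /
# n_samples toward the 50000/25000 defaults for production-grade chains.
seed: 1
workdir: out
design: default
params: default
mcmc:
  n_burnin: 2000
  n_samples: 2000
  n_chains: 2
quantity_models:
  - domain: "mammals_birds:consumption"
    covariates: [manaus, rural, peri_urban, multisited, dry]
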