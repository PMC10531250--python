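# Desk-scale demonstration: synthetic trial with informative parental
# phenotypes, three strategies, linear + Gaussian kernels, 3-fold CV.
sim:
  n_males: 8
  n_females: 40
  crosses_per_female: 2
  n_markers: 200
  n_years: 2
  parental_signal: true
strategies: [NO_Cov, Pmean, BV]
kernels:
  - {name: linear}
  - {name: GK, gamma: 1.0}
cv: {k: 3}
mcmc: {iterations: 600, burn_in: 200, thin: 2}
seed: 7
out_dir: demo_out
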