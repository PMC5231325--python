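# Random-intercept growth mixture, classes differing in intercept (d = 2)
scenario: B2
base_seed: 1
K_max: 10
profiles:
  desk: {n_datasets: 10, n_iter: 5000, burn_in: 1000}
  full: {n_datasets: 50, n_iter: 50000, burn_in: 5000}
criteria:
  - {criterion: RM, alpha: 0.5, psi: 0.05}
  - {criterion: RM, alpha: 0.1, psi: 0.0}
  - {criterion: BIC, k_range: [1, 5]}
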