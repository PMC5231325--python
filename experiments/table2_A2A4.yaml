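# Three-class univariate data, high separation (swap scenario for A3/A4)
scenario: A2
base_seed: 1
K_max: 10
profiles:
  desk: {n_datasets: 20, n_iter: 10000, burn_in: 2000}
  full: {n_datasets: 50, n_iter: 50000, burn_in: 5000}
criteria:
  - {criterion: RM, alpha: 0.1, psi: 0.0}
  - {criterion: RM, alpha: 0.9, psi: 0.05}
  - {criterion: BIC, k_range: [1, 6]}
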