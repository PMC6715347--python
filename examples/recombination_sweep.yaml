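# Steady-state symmetry as a function of a fixed recombination rate between
# the ligand and receptor loci (k+ = 3, gamma = 0.5).
experiment: sweep
seed: 1
out: results/rho_sweep
kinetics: {k_on: 3.0, k_off: 1.0, gamma: 0.5, n_cost: 1}
evolution: {N: 1000, mu: 0.01, sigma: 0.1, max_generations: 20000}
spec:
  parameter: rho
  grid: [0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
  replicates: 3
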