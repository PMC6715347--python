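# The recombination modifier coevolves with the signaling loci from free
# recombination (rho = 0.5); under strong selection for asymmetry (k+ = 10)
# it evolves to tight linkage (rho* near 0).
experiment: linkage
seed: 1
out: results/linkage
kinetics: {k_on: 10.0, k_off: 1.0, gamma: 0.5, n_cost: 1}
evolution:
  N: 1000
  mu: 0.01
  sigma: 0.1
  mu_rho: 0.01
  sigma_rho: 0.1
  max_generations: 20000
spec: {rho_init: 0.5, drift_generations: 1000}
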