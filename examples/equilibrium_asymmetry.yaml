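# Full-scale equilibrium run in the strong self-binding regime
# (k+ = 5, gamma = 0.1): the population splits into two complementary
# signaling roles (s* near 0). Takes a minute or two.
experiment: equilibrium
seed: 1
out: results/equilibrium_e2
kinetics: {k_on: 5.0, k_off: 1.0, gamma: 0.1, n_cost: 1}
evolution: {N: 1000, mu: 0.01, sigma: 0.1, max_generations: 10000}
spec: {init: [1.0, 1.0, 0.0, 0.0], rho: 0.0}
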