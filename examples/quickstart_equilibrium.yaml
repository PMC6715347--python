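# Small, fast demonstration run (~10 s): strong self-binding drives the
# population from symmetric signaling toward two complementary roles.
experiment: equilibrium
seed: 1
out: results/quickstart
kinetics: {k_on: 5.0, k_off: 1.0, gamma: 0.5, n_cost: 1}
evolution:
  N: 200
  mu: 0.01
  sigma: 0.1
  max_generations: 2000
spec: {init: [1.0, 1.0, 0.0, 0.0], rho: 0.0}
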