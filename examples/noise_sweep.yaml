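# Bipartite low-noise recovery sweep (paper profile: k=50)
family: bipartite
d1: 2
d2: 10
sigma_eps_grid: [0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0]
n_grid: [100, 1000]
k_replicates: 50
methods: [glasso, clime, scio, naive]
root_seed: 0
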