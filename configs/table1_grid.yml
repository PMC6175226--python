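# Full factorial grid: the 9 study-size rows x 6 heterogeneity pairs.
# Reduce n_iterations for desk-scale runs; the published design uses 1000.
settings: [1]
size_grid:
  - [5000, 10, 500]
  - [2000, 4, 500]
  - [1000, 2, 500]
  - [5000, 20, 250]
  - [2000, 8, 250]
  - [1000, 4, 250]
  - [5000, 50, 100]
  - [2000, 20, 100]
  - [1000, 10, 100]
heterogeneity_grid:
  - [0.0, 0.0]
  - [0.5, 0.0]
  - [0.0, 0.5]
  - [0.33, 0.33]
  - [0.5, 0.5]
  - [0.67, 0.67]
n_iterations: 200
master_seed: 0
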