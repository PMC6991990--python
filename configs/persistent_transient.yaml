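# Published growing-weight construction b_m = m with the mod-3 eps
# sequence: transient at every N.  Run sizes are implementation defaults.
example: persistent_transient
overrides:
  x0: 1
N_grid: [1, 2, 5, 10]
n_steps: 10000
seeds: [1]
out_dir: out/persistent_transient
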