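# Geometric target with a symmetric +-1 walk and homogeneous two-point
# weights: the noisy chain is geometrically ergodic at every N.  The
# two-point atoms reuse the published transient construction's values;
# run sizes are implementation defaults.
example: homogeneous_geometric
N_grid: [1, 10]
n_steps: 20000
seeds: [1, 2]
out_dir: out/homogeneous_geometric
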