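# The transient homogeneous construction under N-replicate averaging:
# reports the recurrence/drift verdicts along the N grid and the
# crossover point N*.  The N grid and run sizes are implementation
# defaults.
example: averaged_recovery
overrides:
  x0: 1
N_grid: [1, 2, 5, 10, 20]
n_steps: 10000
seeds: [1]
out_dir: out/averaged_recovery
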