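# Batch aggregation run: multiplicative kernel on the coarse p=1 grid,
# stopped at degree of aggregation 0.5 (the gel point for this kernel).
system: batch
kernel: product
beta0: 1.0
p: 1
cells: 21
target_i_agg: 0.5
solver:
  method: adaptive_stiff
  rtol: 1.0e-8
  atol: 1.0e-10
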