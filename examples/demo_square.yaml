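# Reduced end-to-end setup: unit square, parabolic kernel, no-go boundary.
domain:
  type: polygon
  vertices: [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]
distribution:
  family: parabolic
  params: {a: 0.75}
boundary_condition: no_go
N: 10000
M: 50
burn_in: 100
seed: 0
bins: 60
shaper_floor: 0.01
outdir: runs/demo_square
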