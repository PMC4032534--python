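# Toxin-range coexistence diagram: lambda (µm) vs producer inoculum ratio r_C.
# Ridge of maximal three-strain coexistence follows a power law r_C ~ 1/lambda^p.
seed: 1
reps: 20
outdir: runs/power
stages: [sweep, ridge, fitlaw]
scenario:
  id: I
  ratios: [1, 1, 0.1]
sweep:
  x: {param: lambda_, values: [60, 76, 95, 120, 151, 190, 240]}
  y: {param: r_C, values: [0.03, 0.047, 0.073, 0.115, 0.18, 0.28, 0.44, 0.69, 1.0]}
  law: power
  ridge_axis: x
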