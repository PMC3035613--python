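# Example run configuration (all keys optional; defaults reproduce the
# calibrated baseline analysis).
horizon: 3000.0            # min
protocol:
  delta_window: null       # e.g. [3000.0, 3240.0]
  pulses: []               # e.g. [{gene: hes1, magnitude: 5.0, window: [3000.0, 3980.0]}]
  ramps: []                # e.g. [{parameter: "k_d,MRN", v0: 0.0485, v1: 0.00485, window: [1000.0, 2000.0]}]
solver:
  rtol: 1.0e-8
  atol: 1.0e-10
  step: 1.0                # output grid, min
calibration:
  m: 10                    # 2^m Sobol points (full-scale scans use m=14)
  skip: 1
gsa:
  n_samples: 256
  fd_step: 1.0e-3
  cutoff: 0.1
experiments:
  batteries: [delta, pulse, single, pairs]
out_dir: notchfate_out
seed: 1
log_level: INFO
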