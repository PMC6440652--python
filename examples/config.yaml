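# Example run configuration for the hsoed CLI.
# Unknown keys are rejected; omitted keys take the documented defaults.
model: unbuffered
load_factor: 1.0
params:            # kinetic overrides (repository defaults otherwise)
  k_on: 0.02
  k_off: 0.01
input:
  kind: step       # step | double_step | square | constant
  magnitude: 20.0  # μM DOX
  onset: 0.0       # min
  period: null     # min, square inputs only
design:
  u_bounds: [1.0, 30.0]   # feasible input band, μM
  t_f: 3000.0             # experiment duration, min
  n_m: 50                 # sampled time points
  n_m_grid: [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
  lam: 0.8                # measurement-cost coefficient λ
hs:
  hms: 15
  hmcr: 0.8        # 0.2 for coarse screening, 0.8 for nested OED
  par: 0.2
  bandwidth_frac: 0.05
  max_iter: 2000
noise:
  sigma_rel: 0.05
  sigma_floor: 0.001
  clip_negative: false
free_params: [k_on, k_off]
seed: 1
out_dir: hsoed_out
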