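# Reference configuration: every key the config loader accepts, at its
# package default.  An empty config file is equivalent to this one.
variant: G0              # G0 | GD | GR | GRC
n: 1
m: 1
d: 0.0                   # gap-junctional coupling (1/s); or low|moderate|high
noise: none              # low|moderate|high|none, or {sigma_ip3, sigma_jinf, sigma_t1}
means:
  t1: 60.0               # s, stimulus onset
  i_ip3_max: 1.8         # uM, plateau [InsP3]
  i_jinf_max: 0.9        # nM/s, plateau Ca2+ influx
regions: []              # GD only: rectangular blocks with their own triples
center:                  # GRC only
  zone: [3, 3]
  sds: {sigma_ip3: 0.01, sigma_jinf: 0.001, sigma_t1: 0.0}
  t1_mode: min_background
graph: {p: 0.0, holes_q: 0.0, edge_rule: mean}
params:                  # single-cell constants (nM, s; log10 scale for mu/sigma)
  gamma: 450.0
  re1: 0.17
  re2: 18.8
  rs1: 0.27
  rs2: 26.5
  sigma_bell: 0.3        # log10-nM width of the InsP3R bell (see docs/methods.md)
  ri1: 1300.0
  mu_min: 2.4
  mu_max: 2.18
  rim_min: 821.3
  rim_max: 24.3
  ri2_min: 6352.0
  ri2_max: 7042.0
  Kb: 1.0
  beta: 2.5
  K_ip3: 6.0
  K_jinf: 6.0
  x0: 110.0
  y0: 260000.0
  ip3_baseline: 0.015
  jinf_baseline: 0.1
t_end: 600.0
output_dt: 0.5
rtol: 1.0e-6
atol: 1.0e-9
method: RK45
n_bins: 10
seed: 0
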