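# Reference two-module experiment: generate the 485-cell network,
# simulate basal / cholinergic / beta-adrenergic states, report
# per-module cycle lengths, leadership and the rate range.
network:
  module_sizes:
  - 243
  - 242
  degree_cap: 5
  resistance_MOhm: 3750.0
modules:
  '0':
    g_CaL: 0.52
    P_up: 9.0
  '1':
    g_CaL: 0.3
    P_up: 12.0
simulation:
  duration_s:
    basal: 8.0
    ChR: 16.0
    beta_AR: 8.0
  dt_ms: 0.005
  record_stride: 200
  transient_discard_s:
    basal: 2.0
    ChR: 8.0
    beta_AR: 2.0
modes:
- basal
- ChR
- beta_AR
seed: 1
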