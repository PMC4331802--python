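name: two_cycles_nc_nc
dims:
- 10
flow_mode: through
flow_rate: 0.02
diffusion_rate: 0.0
chemotaxis_rate: 0.0
substeps: 1
stage2_order:
- flow
- diffusion
- chemotaxis
cell_diffusion: false
stochastic: false
generations: 3500
seeds:
- 0
record_every: 1
inflow:
  N: 50000.0
substrates:
  N:
    uniform: 2000.0
  S1:
    uniform: 500.0
  S2:
    uniform: 500.0
  S3:
    uniform: 500.0
  S4:
    uniform: 500.0
  S5:
    uniform: 500.0
  S6:
    uniform: 500.0
mutation: null
species:
- id: P1
  consumed:
  - N
  - S1
  produced:
    S2: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S1: 6.0
    weights:
      N: 1.0
      S1: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S2: 7.0
  genes:
  - id: e_S1
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S1
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
- id: P2
  consumed:
  - N
  - S2
  produced:
    S3: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S2: 6.0
    weights:
      N: 1.0
      S2: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S3: 7.0
  genes:
  - id: e_S2
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S2
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
- id: P3
  consumed:
  - N
  - S3
  produced:
    S1: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S3: 6.0
    weights:
      N: 1.0
      S3: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S1: 7.0
  genes:
  - id: e_S3
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S3
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
- id: P4
  consumed:
  - N
  - S4
  produced:
    S5: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S4: 6.0
    weights:
      N: 1.0
      S4: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S5: 7.0
  genes:
  - id: e_S4
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S4
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
- id: P5
  consumed:
  - N
  - S5
  produced:
    S6: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S5: 6.0
    weights:
      N: 1.0
      S5: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S6: 7.0
  genes:
  - id: e_S5
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S5
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
- id: P6
  consumed:
  - N
  - S6
  produced:
    S4: true
  activators: []
  inhibitors: []
  strategy: non-compensatory
  params:
    c:
      N: 1.0
      S6: 6.0
    weights:
      N: 1.0
      S6: 1.0
    k_max: 1.0
    e:
      N: 1.0
    yields:
      S4: 7.0
  genes:
  - id: e_S6
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S6
    support:
    - 0.9
    freqs:
    - 1.0
  initial_count:
    uniform: 2000.0
schedule:
- generation: 100
  type: horizontal_transfer
  node: 0
  donor: P6
  acceptor: P1
  slot: e_S6
  n_cells: 100.0
  new_species_id: P7
- generation: 2000
  type: scale_inflow
  factor: 0.01
- generation: 3000
  type: set_inflow
  composition:
    N: 50000.0
format_version: 1
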