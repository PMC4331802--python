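name: poisoner_prey
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
generations: 900
seeds:
- 0
record_every: 1
inflow:
  N1: 40000.0
substrates:
  N1:
    uniform: 500.0
  S1:
    uniform: 0.0
  S2:
    uniform: 0.0
mutation: null
species:
- id: prey
  consumed:
  - N1
  produced:
    S1: true
  activators: []
  inhibitors:
  - S2
  strategy: non-compensatory
  params:
    c:
      N1: 1.0
    k_max: 2.0
    e:
      N1: 1.0
    yields:
      S1: 10.0
    death_rate: 0.04
  genes:
  - id: s_S2
    role: sensitivity
    bounds:
    - 0.0
    - 10.0
    target: S2
    support:
    - 0.025
    - 0.25
    freqs:
    - 0.5
    - 0.5
  initial_count:
    uniform: 500.0
- id: poisoner
  consumed:
  - N1
  - S1
  produced:
    S2: true
  activators:
  - S1
  inhibitors: []
  strategy: compensatory
  params:
    c:
      N1: 1.0
      S1: 3.0
    weights:
      N1: 1.0
      S1: 1.0
    k_max: 1.0
    e:
      N1: 1.0
    yields:
      S2: 0.0002
    a: 0.0001
    death_rate: 0.01
  genes:
  - id: e_S1
    role: utilization-efficiency
    bounds:
    - 0.01
    - 1.0
    target: S1
    support:
    - 0.2
    - 0.8
    freqs:
    - 0.5
    - 0.5
  initial_count:
    uniform: 500.0
schedule: []
format_version: 1
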