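activities:
- name: Idle
  mean_dwell_minutes: 25.0
  hourly_weights:
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.5
- name: Leaving
  mean_dwell_minutes: 150.0
  hourly_weights:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 1.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.0
  - 0.0
- name: Toileting
  mean_dwell_minutes: 4.0
  hourly_weights:
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.5
- name: Showering
  mean_dwell_minutes: 9.0
  hourly_weights:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 2.0
  - 3.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- name: Sleeping
  mean_dwell_minutes: 420.0
  hourly_weights:
  - 4.0
  - 4.0
  - 4.0
  - 4.0
  - 4.0
  - 4.0
  - 4.0
  - 0.5
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 2.0
  - 4.0
- name: Breakfast
  mean_dwell_minutes: 16.0
  hourly_weights:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 2.0
  - 3.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- name: Lunch
  mean_dwell_minutes: 25.0
  hourly_weights:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 3.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- name: SpareTime
  mean_dwell_minutes: 130.0
  hourly_weights:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 0.5
sensor_ids:
- bed
- bedroom_pir
- bathroom_door
- toilet_flush
- shower
- bathroom_pir
- fridge
- cupboard
- microwave
- kitchen_pir
- front_door
- living_pir
fire_prob:
- - 0.02
  - 0.05
  - 0.02
  - 0.01
  - 0.0
  - 0.03
  - 0.03
  - 0.03
  - 0.01
  - 0.1
  - 0.01
  - 0.3
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.04
  - 0.0
- - 0.02
  - 0.1
  - 0.7
  - 0.4
  - 0.02
  - 0.8
  - 0.01
  - 0.01
  - 0.0
  - 0.02
  - 0.0
  - 0.05
- - 0.01
  - 0.05
  - 0.35
  - 0.05
  - 0.9
  - 0.8
  - 0.0
  - 0.0
  - 0.0
  - 0.01
  - 0.0
  - 0.02
- - 0.95
  - 0.1
  - 0.01
  - 0.0
  - 0.0
  - 0.01
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.01
  - 0.02
  - 0.01
  - 0.0
  - 0.0
  - 0.01
  - 0.4
  - 0.5
  - 0.25
  - 0.9
  - 0.0
  - 0.1
- - 0.01
  - 0.02
  - 0.01
  - 0.0
  - 0.0
  - 0.01
  - 0.45
  - 0.45
  - 0.35
  - 0.9
  - 0.0
  - 0.1
- - 0.01
  - 0.03
  - 0.02
  - 0.01
  - 0.0
  - 0.02
  - 0.05
  - 0.02
  - 0.01
  - 0.08
  - 0.01
  - 0.85
n_days: 14
dt: 60.0
noise_flip_prob: 0.02
dwell_mode: geometric
lognormal_sigma: 0.6
start: '2012-01-02 00:00:00'
seed: 0
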