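# Six-chamber untreated demo device: three empty references (top row, with
# the hour-long lifetime drift) and three consuming spheroids (bottom row).
# Run with:  spheroxi run --config examples/demo.yaml --out scratch/demo
seed: 1
scene:
  image_shape: [150, 220]
  pixel_size: 4.0            # um/px
  chamber_centers:
    - [40, 40]
    - [40, 110]
    - [40, 180]
    - [110, 40]
    - [110, 110]
    - [110, 180]
  occupancy: [empty, empty, empty, spheroid, spheroid, spheroid]
  chamber_diameter: 200.0    # um
  chamber_height: 300.0      # um
  spheroid_diameter: 115.0   # um
  spheroid_core_fraction: 1.0
acquisition:
  modulation_frequency: 250000.0
  n_phase_steps: 16
  exposure_time: 0.5
  n_timepoints: 13
  time_interval: 5.0
  photon_budget: 10000.0
  read_noise_sd: 2.0
kinetics:
  o2_initial: 19.2           # % O2 at sealing
  o2_plateau: 13.8           # % O2
  onset_delay: 0.0           # min
  tau_e_initial: 371.3       # ns, empty-chamber lifetime at t=0
  reference_drift: 6.4       # ns lost over the hour
calibration:
  tau_n: 533.0               # ns, nitrogen reference
  tau_a: 381.0               # ns, air reference
  o2_a: 20.9                 # % O2
analysis:
  rate_window: 5             # points, 0-20 min
  plateau_window: 7          # points, 30-60 min
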