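# Full demo run: simulate a 30-well screening plate (one control and two
# crispant groups), extract per-flash kinematics, classify responses and
# test group proportions against the scrambled control.
seed: 1
plate_map: demo_plate.csv
schedule:
  paradigm: flash_series
  start: 70
  acclimation: 60
simulate:
  params:
    scrambled: {p_seizure: 0.05}
    scn1lab:   {p_seizure: 0.30}
    gabra1:    {p_seizure: 0.12}
classifier:
  md_threshold: 2.5
  p_threshold: 0.1
  moving_quantile: 0.0
reference_group: scrambled
alternative: greater
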