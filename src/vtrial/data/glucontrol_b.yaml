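# Glucontrol Group B (conventional) insulin protocol, target 7.8-10.0 mmol/L.
# Same layout as glucontrol_a.yaml.
name: glucontrol_b
target: [7.8, 10.0]
starting:
  - [0.0, 10.0, hold]
  - [10.0, 13.9, rate, 1.0]
  - [13.9, 16.7, rate, 2.0]
  - [16.7, inf, rate, 4.0]
maintenance:
  - [0.0, 2.2, stop_bolus]
  - [2.2, 4.4, stop]
  - [4.4, 7.8, halve]
  - [7.8, 10.0, target]
  - [10.0, 13.9, increment, 1.0]
  - [13.9, 16.7, increment, 2.0]
  - [16.7, inf, increment, 3.0]
hypoglycemia:
  bolus_g: 10.0
  resume_threshold_mg_dl: 80.0
timing:
  relative_change_threshold: 0.5
  four_hour_rule: literal
  lookback_h: 4
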