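# Glucontrol Group A (intensive) insulin protocol, target 4.4-6.1 mmol/L.
# Bands are [lo, hi) in mmol/L; "inf" means unbounded above.
# Starting actions: [lo, hi, hold] or [lo, hi, rate, U/h].
# Maintenance actions: increment (U/h), target (no change), halve, stop,
# stop_bolus (stop insulin + IV glucose bolus + call physician).
name: glucontrol_a
target: [4.4, 6.1]
starting:
  - [0.0, 6.1, hold]
  - [6.1, 7.8, rate, 1.0]
  - [7.8, 10.0, rate, 2.0]
  - [10.0, inf, rate, 4.0]
maintenance:
  - [0.0, 2.2, stop_bolus]
  - [2.2, 4.4, stop]
  - [4.4, 6.1, target]
  - [6.1, 7.8, increment, 0.5]
  - [7.8, 10.0, increment, 1.0]
  - [10.0, 16.7, increment, 2.0]
  - [16.7, inf, increment, 3.0]
hypoglycemia:
  bolus_g: 10.0
  resume_threshold_mg_dl: 80.0   # hourly measurements until BG exceeds this
timing:
  relative_change_threshold: 0.5
  four_hour_rule: literal        # or: sustained
  lookback_h: 4
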