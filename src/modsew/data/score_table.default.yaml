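# Default severity band tables (five bands -> scores 0..4 per variable).
# PLACEHOLDER cut-points in the style of the Marshall organ dysfunction
# score; the reference table this stands in for is not publicly printed.
# higher_worse: score = number of thresholds strictly below the value.
# lower_worse:  score = number of thresholds at or above the value.
bilirubin:
  direction: higher_worse
  thresholds: [20.0, 60.0, 120.0, 240.0]
creatinine:
  direction: higher_worse
  thresholds: [100.0, 200.0, 350.0, 500.0]
dopamine:
  direction: higher_worse
  thresholds: [0.0, 5.0, 10.0, 15.0]
gcs:
  direction: lower_worse
  thresholds: [14.0, 12.0, 9.0, 6.0]
heart_rate:
  direction: higher_worse
  thresholds: [100.0, 120.0, 140.0, 160.0]
lactate:
  direction: higher_worse
  thresholds: [2.0, 3.5, 5.0, 8.0]
oxygenation_index:
  direction: lower_worse
  thresholds: [300.0, 225.0, 150.0, 75.0]
platelets:
  direction: lower_worse
  thresholds: [120.0, 80.0, 50.0, 20.0]
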