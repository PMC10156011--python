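# Example simulated listener for the 2IFC pitch-change detection task:
# emovox staircase --observer configs/observer_psychometric.yaml --seed 1
kind: psychometric
threshold_cents: 80.0   # native-language 70.7%-correct pitch shift
slope: 4.5              # probit units per octave of shift magnitude
lapse_rate: 0.02
familiarity: 1.0
familiarity_gain: 1.2   # native/foreign sensitivity ratio (the LFE)
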