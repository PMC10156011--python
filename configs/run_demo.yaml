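# Full-pipeline demo configuration: emovox run-all --config configs/run_demo.yaml
seed: 1
output_dir: emovox_run
sample_rate: 22050
# cohort sizes per experiment (FR/JP native speakers)
n_fr: 20
n_jp: 21
n_fr_exp2: 24
n_jp_exp2: 20
# population-level observer parameters; individual participants get
# lognormal variation around these (see docs/methods.md)
exp1_observer: {}
exp2_observer: {}
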