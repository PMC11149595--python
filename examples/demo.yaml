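# Demo pipeline configuration: full synthetic run, all stages.
out_dir: demo_out
seed: 7
stages: [simulate, dose, respond, analyze]
n_patients: 35
n_boot: 1000
volume_mode: baseline
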