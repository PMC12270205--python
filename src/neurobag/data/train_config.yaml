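# Staged training protocol defaults (mirrors neurobag.net.TrainConfig)
cycles: 5
epochs_per_cycle: 15
batch_size: 8
lr0: 5.0e-6
lr_decay: 0.7
patience: 6
seed: 42
init_head_bias: true
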