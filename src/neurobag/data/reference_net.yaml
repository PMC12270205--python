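# Frozen full-scale reference architecture (mirrors neurobag.net.REFERENCE_CONFIG)
# Total trainable parameters: 251,098,737
stem_width: 448
stem_kernel: 5
stem_stride: 2
block_layers: [3, 6, 12, 8]
growth_rate: 156
bottleneck_scale: 1
compression: 0.5
final_conv_width: 156
stem_bias: true
final_bias: true
bottleneck_bias: false
growth_bias: false
transition_bias: false
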