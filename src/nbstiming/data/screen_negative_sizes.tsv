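category	n
early	90060
standard	305674
late	19135
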