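{"units": "mm", "vertices": [[-2.0, 28.0], [2.0, 28.0], [2.5, 30.5], [0.0, 32.0], [-2.5, 30.5]]}
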