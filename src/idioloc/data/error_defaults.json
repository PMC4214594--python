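{"sigma_theta": 0.05, "sigma_step": 0.16}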