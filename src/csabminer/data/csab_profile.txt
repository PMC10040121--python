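CX2−18CX3CX2−10[GAPSIDERYW]X1CX4−17CXC
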