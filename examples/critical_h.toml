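# locate the period blow-up accumulation point at g = 1.5, fixed inputs
[model]
g = 1.5
gain_mode = "hard_rectify"

[forcing]
protocol = "fixed"
J_max = 10.0

[run]
mode = "critical"
g = 1.5
h = 4.25
h_bracket = [4.2, 4.3]
output_dir = "out"
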