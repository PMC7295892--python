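# classify the swap-forced subunit at strong inhibition
[model]
g = 25.0
h = 1.0
gain_mode = "hard_rectify"

[forcing]
protocol = "swap"
f_s = 1.5
J_max = 10.0

[run]
mode = "classify"
g = 25.0
h = 1.0
output_dir = "out"
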