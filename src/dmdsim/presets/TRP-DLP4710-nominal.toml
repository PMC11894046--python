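label = "TRP-DLP4710-nominal"
pitch_um = 5.4
width_um = 4.968000000000001
axis_plus = [0.9972495757785845, 0.0, 0.07411668914241404]
axis_minus = [0.0, -0.9972495757785845, 0.07411668914241404]
gamma_plus_deg = 16.954783328140312
gamma_minus_deg = 16.954783328140312
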