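label = "TRP-DLP4710-fitted"
pitch_um = 5.4
width_um = 4.968000000000001
axis_plus = [0.9716901337584277, 0.22433234351536468, 0.07411668914241404]
axis_minus = [0.22433234351536468, -0.9716901337584277, 0.07411668914241404]
gamma_plus_deg = 17.7
gamma_minus_deg = 17.7
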