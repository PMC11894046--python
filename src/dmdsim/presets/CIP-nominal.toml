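label = "CIP-nominal"
pitch_um = 7.56
width_um = 6.9552
axis_plus = [0.7071067811865475, 0.7071067811865475, 0.0]
axis_minus = [0.7071067811865475, 0.7071067811865475, 0.0]
gamma_plus_deg = 12.0
gamma_minus_deg = -12.0
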