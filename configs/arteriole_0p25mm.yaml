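# phantom preset: 0.25 mm arteriole channel
arteriole_diameter_mm: 0.25
arteriole_angle_deg: 0.0
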