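"""Physical constants."""

#: Vacuum speed of light, m/s.
C0 = 299_792_458.0

#: Vacuum wave impedance, ohms.
ETA0 = 376.730313668
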