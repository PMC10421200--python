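2
Lattice="30.000000 0.0 0.0 0.0 30.000000 0.0 0.0 0.0 30.000000" pbc="F F F"
X         0.00000000      0.00000000      7.50000000
X         0.00000000      0.00000000      8.50000000
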