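# Van der Waals radii (Angstrom), Bondi-style values used for grid-cube
# occupancy.  Elements not listed fall back to `default`.
default: 1.70
H: 1.10
C: 1.70
N: 1.55
O: 1.52
F: 1.47
P: 1.80
S: 1.80
Cl: 1.75
Br: 1.85
I: 1.98
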