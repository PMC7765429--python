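# van der Waals radii (Å) for solvent-accessible surface computation.
# Main-group values: Bondi (1964); metals: Batsanov-style working values.
# element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
Cl	1.75
Br	1.85
I	1.98
B	1.92
Se	1.90
Si	2.10
Na	2.27
K	2.75
Mg	1.73
Ca	2.31
Mn	2.05
Fe	2.05
Co	2.00
Ni	1.97
Cu	1.96
Zn	2.01
Cd	2.18
Hg	2.05
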