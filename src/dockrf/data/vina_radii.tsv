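# AutoDock Vina atom-type radii (Å) used for surface distances in the
# energy terms; metals use the Vina metal-donor radius.
# element	radius
C	1.9
N	1.8
O	1.7
S	2.0
P	2.1
F	1.5
Cl	1.8
Br	2.0
I	2.2
B	1.9
Se	2.0
Si	2.2
Na	1.2
K	1.2
Mg	1.2
Ca	1.2
Mn	1.2
Fe	1.2
Co	1.2
Ni	1.2
Cu	1.2
Zn	1.2
Cd	1.2
Hg	1.2
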