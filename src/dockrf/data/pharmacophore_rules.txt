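# Pharmacophore typing rules, v1.
# One rule per line: LABEL <TAB> PATTERN, scanned top to bottom; the first
# matching rule labels the atom.
#
# Pattern grammar:
#   PATTERN   := PARENT CLAUSE*
#   PARENT    := SYBYL type ("N.4") or bare element ("O" matches any oxygen)
#   CLAUSE    := "(" [COUNT] TYPES CLAUSE* ")"   atoms that MUST be bonded
#              | "[" [COUNT] TYPES CLAUSE* "]"   atoms that must NOT be bonded
#   TYPES     := TYPE | "(" TYPE (or TYPE)* ")" | "*"
# A required clause needs at least COUNT (default 1) bonded atoms matching;
# its bond count includes the bond back to the parent when nested.  A
# forbidden clause with a COUNT fails the rule when COUNT or more neighbours
# match; without a COUNT it fails when any neighbour not already consumed by
# a required clause matches.  "H" matches explicit hydrogens, or implied
# hydrogens (valence deficit) when the molecule carries none.
P	N.4 (4 *)
P	N.2 (3 *)
P	N.pl3 (C.cat)
N	O (C (2 (O or S) [*]))
N	O (P (2 (O or S) [*]))
N	O (S (3 O [*]))
N	S (C (4 *)) [*]
N	S (C (2 (O or S) [*]))
DA	O (H)
DA	N.3 (H)
DA	N.2 (H)
DA	N.pl3 (H)
DA	S (H)
D	N.ar (H)
D	N.am (H)
A	O
A	N.3
A	N.1
A	N.ar (2 *)
A	N.pl3
A	S [3 *]
AR	N.ar
AR	C.ar
H	C [N] [O] [F] [P] [S]
PL	N.am
PL	S (3 *)
# polar carbon: bonded to at least one of N/O/F/P/S (complement of the
# hydrophobic-carbon rule above)
PL	C ((N or O or F or P or S))
PL	P
HA	F
HA	Cl
HA	Br
HA	I
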