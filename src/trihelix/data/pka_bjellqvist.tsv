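# Bjellqvist pKa set (ExPASy-compatible). group: nterm/cterm terminus or a
# residue one-letter code; charge: +1 basic, -1 acidic at low pH side.
group	pka	charge
nterm	7.5	1
cterm	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.0	-1
Y	10.0	-1
H	5.98	1
K	10.0	1
R	12.0	1
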