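# E. coli K-12 codon usage, relative frequency per synonymous-codon family.
# Columns: amino_acid <TAB> codon <TAB> frequency
# Frequencies are renormalized per amino acid on load.
A	GCG	0.36
A	GCC	0.27
A	GCA	0.21
A	GCT	0.16
C	TGC	0.56
C	TGT	0.44
D	GAT	0.63
D	GAC	0.37
E	GAA	0.69
E	GAG	0.31
F	TTT	0.57
F	TTC	0.43
G	GGC	0.40
G	GGT	0.34
G	GGG	0.15
G	GGA	0.11
H	CAT	0.57
H	CAC	0.43
I	ATT	0.51
I	ATC	0.42
I	ATA	0.07
K	AAA	0.76
K	AAG	0.24
L	CTG	0.50
L	TTA	0.13
L	TTG	0.13
L	CTT	0.10
L	CTC	0.10
L	CTA	0.04
M	ATG	1.00
N	AAC	0.55
N	AAT	0.45
P	CCG	0.52
P	CCA	0.20
P	CCT	0.16
P	CCC	0.12
Q	CAG	0.65
Q	CAA	0.35
R	CGC	0.40
R	CGT	0.38
R	CGG	0.10
R	CGA	0.06
R	AGA	0.04
R	AGG	0.02
S	AGC	0.28
S	TCC	0.15
S	TCG	0.15
S	AGT	0.15
S	TCT	0.15
S	TCA	0.12
T	ACC	0.44
T	ACG	0.27
T	ACT	0.16
T	ACA	0.13
V	GTG	0.37
V	GTT	0.28
V	GTC	0.20
V	GTA	0.15
W	TGG	1.00
Y	TAT	0.57
Y	TAC	0.43
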