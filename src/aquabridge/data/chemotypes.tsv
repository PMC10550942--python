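# Polar-site chemotypes for the 20 standard amino acids (side chains).
# Backbone amide N / carbonyl O / OXT and waters are handled by built-in
# rules; sulphur is never emitted as a polar site.
# columns: res_name  atom  role  hybridization  h_rule  parent  aux
# role: donor|acceptor|both. aux atoms (| separated) define the sp2 plane,
# the hydroxyl torsion reference, or the staggering reference.
SER	OG	both	sp3	hydroxyl	CB	CA
THR	OG1	both	sp3	hydroxyl	CB	CA
TYR	OH	both	sp3	hydroxyl	CZ	CE1
ASN	OD1	acceptor	sp2	carbonyl	CG	CB
ASN	ND2	donor	sp2	amide2	CG	OD1
GLN	OE1	acceptor	sp2	carbonyl	CD	CG
GLN	NE2	donor	sp2	amide2	CD	OE1
ASP	OD1	acceptor	sp2	carbonyl	CG	OD2
ASP	OD2	acceptor	sp2	carbonyl	CG	OD1
GLU	OE1	acceptor	sp2	carbonyl	CD	OE2
GLU	OE2	acceptor	sp2	carbonyl	CD	OE1
HIS	ND1	both	sp2	ring_n	CG	CE1
HIS	NE2	both	sp2	ring_n_h	CD2	CE1
LYS	NZ	donor	sp3	nh3	CE	CD
ARG	NE	donor	sp2	ring_n_h	CD	CZ
ARG	NH1	donor	sp2	amide2	CZ	NE
ARG	NH2	donor	sp2	amide2	CZ	NE
TRP	NE1	donor	sp2	ring_n_h	CD1	CE2
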