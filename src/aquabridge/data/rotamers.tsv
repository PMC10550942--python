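# Coarse backbone-independent rotamer library: the most frequent
# conformers per residue (gauche+/trans/gauche- chi1 staples with common
# chi2+ extensions).  Deliberately small; richer libraries in the same
# format can be swapped in via configuration.
# columns: res_name  chi_angles (comma separated, degrees; "-" for none)  frequency
ALA	-	1.0
GLY	-	1.0
PRO	-	1.0
SER	60	0.4
SER	-60	0.35
SER	180	0.25
THR	60	0.45
THR	-60	0.35
THR	180	0.2
CYS	-60	0.5
CYS	180	0.3
CYS	60	0.2
VAL	180	0.6
VAL	-60	0.3
VAL	60	0.1
ILE	-60,180	0.6
ILE	-60,-60	0.2
ILE	180,180	0.2
LEU	-60,180	0.6
LEU	180,60	0.3
LEU	-60,-60	0.1
ASP	-60,-15	0.5
ASP	180,15	0.3
ASP	60,-15	0.2
ASN	-60,-30	0.4
ASN	180,30	0.3
ASN	-60,120	0.3
GLU	-60,180,-30	0.4
GLU	180,180,0	0.35
GLU	-60,-60,-30	0.25
GLN	-60,180,-30	0.4
GLN	180,180,0	0.35
GLN	-60,-60,-60	0.25
HIS	-60,-70	0.4
HIS	180,60	0.35
HIS	-60,90	0.25
PHE	-60,90	0.5
PHE	180,90	0.35
PHE	60,90	0.15
TYR	-60,90	0.5
TYR	180,90	0.35
TYR	60,90	0.15
TRP	-60,90	0.4
TRP	180,90	0.35
TRP	-60,-90	0.25
MET	-60,180,180	0.4
MET	180,180,180	0.35
MET	-60,-60,-60	0.25
LYS	-60,180,180,180	0.5
LYS	180,180,180,180	0.35
LYS	-60,180,-60,180	0.15
ARG	-60,180,180,180	0.5
ARG	180,180,180,180	0.35
ARG	-60,180,-60,180	0.15
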