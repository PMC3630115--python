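# Natural amino-acid abundance (McCaldon & Argos, Proteins 1988),
# transcribed as fractional frequencies; renormalized on load.
residue	frequency
A	0.0828
C	0.0170
D	0.0531
E	0.0620
F	0.0391
G	0.0722
H	0.0219
I	0.0533
K	0.0572
L	0.0900
M	0.0238
N	0.0442
P	0.0506
Q	0.0402
R	0.0569
S	0.0695
T	0.0585
V	0.0663
W	0.0131
Y	0.0321
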