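# One-bond/two-bond 2H isotope shifts of 13Ca / 13Cb (ppm) applied to
# perdeuterated samples. Published per-residue-type corrections; values are
# subtracted together with the random-coil reference. Swap via
# shifts.load_reference_table.
# aa	Ca	Cb
A	-0.50	-0.83
C	-0.49	-0.65
D	-0.47	-0.65
E	-0.47	-0.79
F	-0.48	-0.68
G	-0.39
H	-0.47	-0.68
I	-0.55	-0.96
K	-0.47	-0.79
L	-0.50	-0.88
M	-0.47	-0.79
N	-0.47	-0.65
P	-0.47	-0.79
Q	-0.47	-0.79
R	-0.47	-0.79
S	-0.47	-0.65
T	-0.52	-0.78
V	-0.56	-0.98
W	-0.48	-0.68
Y	-0.48	-0.68
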