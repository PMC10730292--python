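# Standard vertebrate mitochondrial gene order, linearized from tRNA-Phe.
# 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus the control region (CR).
# Strand is the coding strand relative to the conventionally deposited
# (majority-coding) strand. template_version: 1
label	ftype	strand
F	tRNA	+
rrnS	rRNA	+
V	tRNA	+
rrnL	rRNA	+
L1	tRNA	+
nad1	PCG	+
I	tRNA	+
Q	tRNA	-
M	tRNA	+
nad2	PCG	+
W	tRNA	+
A	tRNA	-
N	tRNA	-
C	tRNA	-
Y	tRNA	-
cox1	PCG	+
S1	tRNA	-
D	tRNA	+
cox2	PCG	+
K	tRNA	+
atp8	PCG	+
atp6	PCG	+
cox3	PCG	+
G	tRNA	+
nad3	PCG	+
R	tRNA	+
nad4l	PCG	+
nad4	PCG	+
H	tRNA	+
S2	tRNA	+
L2	tRNA	+
nad5	PCG	+
nad6	PCG	-
E	tRNA	-
cob	PCG	+
T	tRNA	+
P	tRNA	-
CR	CR	+
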