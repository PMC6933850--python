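# Monatomic ion components: residue name -> formal charge.
# Positive entries drive the "iod" nearest-positive-ion distance.
NA: 1
K: 1
LI: 1
RB: 1
CS: 1
MG: 2
CA: 2
ZN: 2
MN: 2
FE: 3
FE2: 2
NI: 2
CU: 2
CU1: 1
CO: 2
CD: 2
HG: 2
SR: 2
BA: 2
AL: 3
CL: -1
BR: -1
IOD: -1
F: -1
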