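# Additive per-residue retention coefficients (C18, formic-acid mobile phase).
# The predicted retention time is an affine map of the summed score onto the gradient window.
aa,coeff
A,2.0
C,2.6
D,2.8
E,3.4
F,9.0
G,0.2
H,0.9
I,8.0
K,0.2
L,9.6
M,7.0
N,0.6
P,2.2
Q,0.0
R,0.6
S,0.2
T,1.6
V,5.0
W,11.0
Y,6.1
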