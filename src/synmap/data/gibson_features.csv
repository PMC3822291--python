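symbol,horizontal,vertical,oblique_fwd,oblique_back,curve_closed,curve_open_vert,curve_open_horiz,intersection,symmetry_vert,discontinuity,redundancy
A,1,0,1,1,0,0,0,1,1,0,0
B,0,1,0,0,1,0,0,1,0,0,1
C,0,0,0,0,0,0,1,0,0,1,0
D,0,1,0,0,1,0,0,0,0,0,0
E,1,1,0,0,0,0,0,1,0,1,1
F,1,1,0,0,0,0,0,1,0,1,0
G,1,0,0,0,0,0,1,0,0,1,0
H,1,1,0,0,0,0,0,1,1,0,1
I,0,1,0,0,0,0,0,0,1,0,0
J,0,1,0,0,0,1,0,0,0,1,0
K,0,1,1,1,0,0,0,1,0,0,0
L,1,1,0,0,0,0,0,0,0,0,0
M,0,1,1,1,0,0,0,0,1,0,1
N,0,1,0,1,0,0,0,0,0,0,0
O,0,0,0,0,1,0,0,0,1,0,0
P,0,1,0,0,1,0,0,0,0,1,0
Q,0,0,0,1,1,0,0,1,0,0,0
R,0,1,1,0,1,0,0,1,0,0,0
S,0,0,0,0,0,1,1,0,0,1,1
T,1,1,0,0,0,0,0,1,1,0,0
U,0,1,0,0,0,1,0,0,1,0,0
V,0,0,1,1,0,0,0,0,1,0,0
W,0,0,1,1,0,0,0,0,1,0,1
X,0,0,1,1,0,0,0,1,1,0,0
Y,0,1,1,1,0,0,0,1,1,0,0
Z,1,0,1,0,0,0,0,0,0,0,1
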