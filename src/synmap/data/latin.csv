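symbol,script,position,name_phonemes,familiarity
A,latin,1,eɪ,
B,latin,2,b|iː,
C,latin,3,s|iː,
D,latin,4,d|iː,
E,latin,5,iː,
F,latin,6,ɛ|f,
G,latin,7,dʒ|iː,
H,latin,8,eɪ|tʃ,
I,latin,9,aɪ,
J,latin,10,dʒ|eɪ,
K,latin,11,k|eɪ,
L,latin,12,ɛ|l,
M,latin,13,ɛ|m,
N,latin,14,ɛ|n,
O,latin,15,oʊ,
P,latin,16,p|iː,
Q,latin,17,k|j|uː,
R,latin,18,ɑː|r,
S,latin,19,ɛ|s,
T,latin,20,t|iː,
U,latin,21,j|uː,
V,latin,22,v|iː,
W,latin,23,d|ʌ|b|l|j|uː,
X,latin,24,ɛ|k|s,
Y,latin,25,w|aɪ,
Z,latin,26,z|iː,
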