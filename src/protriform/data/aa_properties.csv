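aa,PAH,PBS,ISA,ECI,KDS,Z3,HWS,MM
A,1.42,0.83,62.90,0.05,1.8,0.09,-0.5,15.03
R,0.98,0.93,52.98,1.69,-4.5,-3.44,3.0,100.14
N,0.67,0.89,17.87,1.31,-3.5,0.84,0.2,58.06
D,1.01,0.54,18.46,1.25,-3.5,2.36,3.0,59.04
C,0.70,1.19,78.51,0.15,2.5,4.13,-1.0,47.10
Q,1.11,1.10,19.53,1.36,-3.5,-1.14,0.2,72.09
E,1.51,0.37,30.19,1.31,-3.5,-0.07,3.0,73.07
G,0.57,0.75,19.93,0.02,-0.4,0.30,0.0,1.01
H,1.00,0.87,87.38,0.56,-3.2,1.11,-0.5,81.10
I,1.08,1.60,149.77,0.09,4.5,-1.03,-1.8,57.11
L,1.21,1.30,154.35,0.10,3.8,-0.98,-1.8,57.11
K,1.16,0.74,102.78,0.53,-3.9,-3.14,3.0,72.13
M,1.45,1.05,132.22,0.34,1.9,-0.41,-1.3,75.15
F,1.13,1.38,189.42,0.14,2.8,0.45,-2.5,91.13
P,0.57,0.55,122.35,0.16,-1.6,2.23,0.0,42.08
S,0.77,0.75,19.75,0.56,-0.8,0.57,0.3,31.03
T,0.83,1.19,59.44,0.65,-0.7,-1.40,-0.4,45.06
W,1.08,1.37,179.16,1.08,-0.9,0.85,-3.4,130.17
Y,0.69,1.47,132.16,0.72,-1.3,0.01,-2.3,107.13
V,1.06,1.70,120.91,0.07,4.2,-1.29,-1.5,43.09
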