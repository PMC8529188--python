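stage,relative_value
VE,0.0
V2,0.40
V3,0.40
V4,0.44
V5,0.60
V6,0.62
V8,0.70
R1,0.70
R2,0.80
R3,1.00
R3.5,1.10
R4,1.20
R4.5,1.30
R5,1.40
R5.5,1.70
R6,1.80
R6.5,1.90
R7,2.00
R7.5,2.40
R8,2.50
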