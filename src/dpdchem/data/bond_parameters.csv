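family,bead_i,bead_j,r_target,r0
MEA,AM2,C2,0.65,0.58
MEA,AM2,OH1,0.68,0.65
TEDA,AM2,EO,0.78,0.73
DEA,AM3',C2,0.67,0.62
DEA,AM3',OH1,0.67,0.64
HEGA,AM3',OH1,0.67,0.64
MEGA,AM3,C2,0.68,0.64
MEGA,AM3,OH',0.68,0.65
XYL,ES,C2,0.60,0.55
XYL,ES,OH',0.65,0.60
XYL,OH',OH',0.45,0.40
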