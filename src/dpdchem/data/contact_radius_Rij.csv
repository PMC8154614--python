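,W,OH1,OH',OH2,ES,EO,AC',C2,C2',T1,T2,AM2,AM3',AM3
W,1.000,0.990,0.975,1.003,1.071,1.058,0.976,1.037,0.998,0.978,1.049,1.086,1.118,1.133
OH1,0.990,0.980,0.965,0.996,1.061,1.048,0.966,1.027,0.988,0.968,1.039,1.076,1.108,1.123
OH',0.975,0.965,0.949,0.981,1.045,1.033,0.951,1.012,0.972,0.952,1.024,1.061,1.093,1.108
OH2,1.003,0.996,0.981,1.012,1.077,1.064,0.982,1.043,1.004,0.984,1.055,1.092,1.124,1.139
ES,1.071,1.061,1.045,1.077,1.141,1.129,1.047,1.108,1.068,1.048,1.120,1.157,1.189,1.204
EO,1.058,1.048,1.033,1.064,1.129,1.116,1.034,1.095,1.056,1.036,1.107,1.144,1.176,1.191
AC',0.976,0.966,0.951,0.982,1.047,1.034,0.952,1.013,0.974,0.954,1.025,1.062,1.094,1.109
C2,1.037,1.027,1.012,1.043,1.108,1.095,1.013,1.074,1.035,1.015,1.086,1.123,1.155,1.170
C2',0.998,0.988,0.972,1.004,1.068,1.056,0.974,1.035,0.995,0.975,1.047,1.084,1.116,1.131
T1,0.978,0.968,0.952,0.984,1.048,1.036,0.954,1.015,0.975,0.955,1.027,1.064,1.096,1.111
T2,1.049,1.039,1.024,1.055,1.120,1.107,1.025,1.086,1.047,1.027,1.098,1.135,1.167,1.182
AM2,1.086,1.076,1.061,1.092,1.157,1.144,1.062,1.123,1.084,1.064,1.135,1.172,1.204,1.219
AM3',1.118,1.108,1.093,1.124,1.189,1.176,1.094,1.155,1.116,1.096,1.167,1.204,1.236,1.251
AM3,1.133,1.123,1.108,1.139,1.204,1.191,1.109,1.170,1.131,1.111,1.182,1.219,1.251,1.266
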