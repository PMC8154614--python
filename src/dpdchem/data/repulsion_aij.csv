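,W,OH1,OH',OH2,ES,EO,AC',C2,C2',T1,T2,AM2,AM3',AM3
W,25.00,18.17,15.09,22.20,22.53,21.81,7.74,45.45,45.50,46.35,45.44,15.57,11.86,13.20
OH1,18.17,14.00,13.86,16.24,18.43,18.17,17.42,27.13,29.76,27.49,26.79,14.63,11.03,11.52
OH',15.09,13.86,14.00,15.95,19.56,19.92,19.42,28.77,29.37,28.85,28.28,14.25,10.62,11.00
OH2,22.20,16.24,15.95,18.00,19.63,20.31,17.42,27.09,27.38,27.59,27.59,16.84,13.20,13.71
ES,22.53,18.43,19.56,19.63,22.00,24.01,22.69,21.50,22.26,21.61,21.67,25.39,22.05,21.97
EO,21.81,18.17,19.92,20.31,24.01,22.50,24.37,23.78,24.49,24.18,24.46,26.86,23.94,23.84
AC',7.74,17.42,19.42,17.42,22.69,24.37,22.50,18.17,19.45,20.38,17.32,26.23,22.87,22.51
C2,45.45,27.13,28.77,27.09,21.50,23.78,18.17,22.00,21.95,22.92,21.97,28.75,21.63,21.83
C2',45.50,29.76,29.37,27.38,22.26,24.49,19.45,21.95,22.00,20.89,21.13,32.32,21.92,22.17
T1,46.35,27.49,28.85,27.59,21.61,24.18,20.38,22.92,20.89,24.00,23.76,29.11,22.00,22.32
T2,45.44,26.79,28.28,27.59,21.67,24.46,17.32,21.97,21.13,23.76,24.00,28.41,21.28,21.56
AM2,15.57,14.63,14.25,16.84,25.39,26.86,26.23,28.75,32.32,29.11,28.41,22.00,21.77,21.89
AM3',11.86,11.03,10.62,13.20,22.05,23.94,22.87,21.63,21.92,22.00,21.28,21.77,22.00,21.98
AM3,13.20,11.52,11.00,13.71,21.97,23.84,22.51,21.83,22.17,22.32,21.56,21.89,21.98,22.00
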