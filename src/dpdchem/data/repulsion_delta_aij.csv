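,W,OH1,OH',OH2,ES,EO,AC',C2,C2',T1,T2,AM2,AM3',AM3
W,0.00,-1.33,-4.41,0.70,-0.97,-1.94,-16.01,21.95,22.00,21.85,20.94,-7.93,-11.64,-10.30
OH1,-1.33,0.00,-0.14,0.24,0.43,-0.08,-0.83,9.13,11.76,8.49,7.79,-3.37,-6.97,-6.48
OH',-4.41,-0.14,0.00,-0.05,1.56,1.67,1.17,10.77,11.37,9.85,9.28,-3.75,-7.38,-7.00
OH2,0.70,0.24,-0.05,0.00,-0.37,0.06,-2.83,7.09,7.38,6.59,6.59,-3.16,-6.80,-6.29
ES,-0.97,0.43,1.56,-0.37,0.00,1.76,0.44,-0.50,0.26,-1.39,-1.33,3.39,0.05,-0.03
EO,-1.94,-0.08,1.67,0.06,1.76,0.00,1.87,1.53,2.24,0.93,1.21,4.61,1.69,1.59
AC',-16.01,-0.83,1.17,-2.83,0.44,1.87,0.00,-4.08,-2.80,-2.87,-5.93,3.98,0.62,0.26
C2,21.95,9.13,10.77,7.09,-0.50,1.53,-4.08,0.00,-0.05,-0.08,-1.03,6.75,-0.39,-0.17
C2',22.00,11.76,11.37,7.38,0.26,2.24,-2.80,-0.05,0.00,-2.11,-1.87,10.32,-0.08,0.17
T1,21.85,8.49,9.85,6.59,-1.39,0.93,-2.87,-0.08,-2.11,0.00,-0.24,6.11,-1.00,-0.68
T2,20.94,7.79,9.28,6.59,-1.33,1.21,-5.93,-1.03,-1.87,-0.24,0.00,5.41,-1.72,-1.44
AM2,-7.93,-3.37,-3.75,-3.16,3.39,4.61,3.98,6.75,10.32,6.11,5.41,0.00,-0.23,-0.11
AM3',-11.64,-6.97,-7.38,-6.80,0.05,1.69,0.62,-0.39,-0.08,-1.00,-1.72,-0.23,0.00,-0.02
AM3,-10.30,-6.48,-7.00,-6.29,-0.03,1.59,0.26,-0.17,0.17,-0.68,-1.44,-0.11,-0.02,0.00
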