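>SYN0001.1 Adf1_like_synthetic
A  [  4   2  88   3   4   6   3   5 ]
C  [  6  90   4   5  86   4   5  84 ]
G  [ 85   4   4  87   6   5  87   6 ]
T  [  5   4   4   5   4  85   5   5 ]
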