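id,mz,suffix,sensitivity,specificity,auc
1,497.26,,0.79,0.64,0.79
2,923.45,,0.65,0.66,0.72
3,761.37,,0.63,0.7,0.7
4,425.25,a,0.66,0.66,0.69
5,722.37,,0.58,0.6,0.66
6,585.3,,0.59,0.55,0.65
7,458.25,,0.55,0.64,0.65
8,747.3,,0.67,0.63,0.63
9,555.27,,0.63,0.6,0.63
10,442.23,,0.59,0.7,0.62
11,546.27,,0.56,0.56,0.62
12,879.43,,0.5,0.56,0.61
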