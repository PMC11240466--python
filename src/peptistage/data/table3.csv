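model,phase,components,sensitivity,specificity,auc
A,train,1-2;5-6,0.875,0.915,0.915
A,test,1-2;5-6,0.286,0.875,0.84
B,train,1-2;4-6,0.858,0.783,0.919
B,test,1-2;4-6,0.286,0.875,0.76
C,train,1-2;5-7,0.858,0.75,0.913
C,test,1-2;5-7,0.429,0.875,0.804
D,train,1-3;5-6,0.875,0.742,0.912
D,test,1-3;5-6,0.429,0.875,0.77
E,train,1-6,0.917,0.758,0.915
E,test,1-6,0.429,0.875,0.77
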