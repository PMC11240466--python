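seq,b_index,b,y,y_index
D,1,116.03481,761.38342,7
L,2,229.11888,646.35648,6
V,3,328.18729,533.27242,5
P,4,425.24005,434.204,4
G,5,482.26152,337.15124,3
N,6,596.30444,280.12978,2
F,7,743.37286,166.08685,1
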