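Repeat,PAR,Y(II),Y(NPQ),Y(NO),qN,qP,ETR,FvFm
1,198,0.124,0.62,0.256,0.879,0.51,10.3,0.5986
2,198,0.129,0.595,0.276,0.873,0.571,10.7,0.5630
3,198,0.137,0.565,0.298,0.851,0.568,11.4,0.5583
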