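>pou_like synthetic stand-in, pou-type octamer consensus
A [  85   5   5   5  85  85  85   5 ]
C [   5   5   5  85   5   5   5   5 ]
G [   5   5  85   5   5   5   5   5 ]
T [   5  85   5   5   5   5   5  85 ]
>sox_like synthetic stand-in, sox-type consensus
A [   5  85   5   5   5   5   5 ]
C [  85   5   5   5   5   5   5 ]
G [   5   5   5   5  85   5   5 ]
T [   5   5  85  85   5  85  85 ]
>pou_sox_double synthetic stand-in, sox-pou composite consensus
A [   5  85   5   5   5   5   5  85   5   5   5  85  85  85   5 ]
C [  85   5   5   5   5   5   5   5   5   5  85   5   5   5   5 ]
G [   5   5   5   5  85   5   5   5   5  85   5   5   5   5   5 ]
T [   5   5  85  85   5  85  85   5  85   5   5   5   5   5  85 ]
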