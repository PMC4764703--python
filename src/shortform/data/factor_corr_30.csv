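,BehAvd,DisAvr,Procst,DstSup,RepDny,DisEndr
BehAvd,1.00,0.71,0.63,0.45,0.49,-0.17
DisAvr,0.71,1.00,0.45,0.41,0.54,-0.14
Procst,0.63,0.45,1.00,0.11,0.59,-0.37
DstSup,0.45,0.41,0.11,1.00,0.14,0.46
RepDny,0.49,0.54,0.59,0.14,1.00,-0.31
DisEndr,-0.17,-0.14,-0.37,0.46,-0.31,1.00
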