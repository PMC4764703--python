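,BehAvd,DisAvr,Procst,DstSup,RepDny,DisEndr
BehAvd,1.00,0.71,0.58,0.53,0.49,-0.12
DisAvr,0.71,1.00,0.43,0.51,0.53,-0.07
Procst,0.58,0.43,1.00,0.18,0.62,-0.32
DstSup,0.53,0.51,0.18,1.00,0.20,0.38
RepDny,0.49,0.53,0.62,0.20,1.00,-0.30
DisEndr,-0.12,-0.07,-0.32,0.38,-0.30,1.00
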