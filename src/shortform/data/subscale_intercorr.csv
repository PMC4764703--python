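,BehAvd,DisAvr,Procst,DstSup,RepDny,DisEndr
BehAvd,,0.542,0.455,0.390,0.372,-0.110
DisAvr,0.618,,0.336,0.345,0.439,-0.115
Procst,0.480,0.352,,0.056,0.481,-0.356
DstSup,0.479,0.468,0.136,,0.165,0.354
RepDny,0.419,0.438,0.529,0.224,,-0.202
DisEndr,-0.093,-0.023,-0.247,0.282,-0.100,
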