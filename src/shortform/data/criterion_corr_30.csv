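,BehAvd,DisAvr,Procst,DstSup,RepDny,DisEndr
identifyTAS,0.430,0.524,0.497,0.098,0.742,-0.321
describeTAS,0.356,0.348,0.454,0.054,0.704,-0.304
AAQ2,0.485,0.609,0.552,0.061,0.666,-0.363
GHQ,0.338,0.432,0.421,0.004,0.499,-0.288
SWL,-0.052,-0.170,-0.211,0.231,-0.065,0.447
emoWB,-0.081,-0.200,-0.296,0.283,-0.211,0.561
psychWB,-0.072,-0.075,-0.234,0.306,-0.144,0.581
socialWB,0.046,0.041,-0.054,0.256,0.102,0.370
strvImportance,0.012,0.040,-0.167,0.207,-0.220,0.327
strvAutonomous,0.079,0.129,-0.114,0.273,-0.087,0.342
strvControlled,0.319,0.358,0.312,0.120,0.424,-0.110
strvProgress,0.003,0.049,-0.142,0.194,0.027,0.300
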