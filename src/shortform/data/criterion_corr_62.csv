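,BehAvd,DisAvr,Procst,DstSup,RepDny,DisEndr
identifyTAS,0.444,0.505,0.515,0.168,0.757,-0.192
describeTAS,0.375,0.350,0.462,0.110,0.701,-0.234
AAQ2,0.499,0.596,0.563,0.152,0.682,-0.217
GHQ,0.357,0.410,0.438,0.070,0.519,-0.184
SWL,-0.053,-0.128,-0.193,0.190,-0.073,0.423
emoWB,-0.075,-0.146,-0.278,0.232,-0.227,0.513
psychWB,-0.052,-0.034,-0.224,0.265,-0.148,0.577
socialWB,0.048,0.063,-0.031,0.238,0.095,0.384
strvImportance,0.011,0.085,-0.169,0.187,-0.243,0.331
strvAutonomous,0.090,0.184,-0.105,0.259,-0.084,0.379
strvControlled,0.333,0.380,0.314,0.157,0.447,-0.045
strvProgress,0.019,0.062,-0.142,0.175,0.023,0.329
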