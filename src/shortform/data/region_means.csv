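region,subscale,mean_62,sd_62,mean_30,sd_30
Midwest,BehAvd,3.65,0.77,3.57,0.84
Midwest,DisAvr,3.68,0.74,3.49,0.88
Midwest,Procst,3.15,0.87,3.13,0.86
Midwest,DstSup,4.06,0.73,4.11,0.76
Midwest,RepDny,2.68,0.76,2.66,0.89
Midwest,DisEndr,4.45,0.63,4.63,0.75
Northeast,BehAvd,3.62,0.78,3.53,0.84
Northeast,DisAvr,3.70,0.77,3.51,0.91
Northeast,Procst,3.17,0.90,3.16,0.89
Northeast,DstSup,4.01,0.76,4.06,0.79
Northeast,RepDny,2.67,0.80,2.63,0.95
Northeast,DisEndr,4.43,0.68,4.59,0.80
Pacific,BehAvd,3.77,0.69,3.72,0.83
Pacific,DisAvr,3.80,0.74,3.49,0.81
Pacific,Procst,3.51,0.93,3.52,0.95
Pacific,DstSup,4.14,0.66,4.17,0.73
Pacific,RepDny,2.67,0.49,2.66,0.60
Pacific,DisEndr,4.44,0.56,4.55,0.73
South,BehAvd,3.70,0.80,3.63,0.85
South,DisAvr,3.72,0.78,3.54,0.92
South,Procst,3.13,0.89,3.12,0.88
South,DstSup,4.14,0.76,4.20,0.79
South,RepDny,2.68,0.82,2.64,0.96
South,DisEndr,4.52,0.63,4.70,0.76
West,BehAvd,3.65,0.78,3.57,0.85
West,DisAvr,3.69,0.78,3.49,0.92
West,Procst,3.17,0.87,3.16,0.86
West,DstSup,4.05,0.77,4.11,0.79
West,RepDny,2.67,0.77,2.63,0.90
West,DisEndr,4.50,0.64,4.66,0.77
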