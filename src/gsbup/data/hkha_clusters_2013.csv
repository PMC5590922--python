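dmu_id,period,DI1,DI2,UI1,DO1,DO2,DO3,UO1
HKEC,2013,7226,3031,82.7,1187.01,248.93,1598.69,21.8
HKWC,2013,7349,3135,74.2,1137.18,132.56,1374.04,16.2
KCC,2013,8899,3547,87.2,1663.34,206.21,1979.47,26.8
KEC,2013,6484,2371,85.9,902.60,315.83,1930.08,23.7
KWC,2013,14076,6587,83.1,2430.17,580.13,3667.01,23.7
NTEC,2013,10096,4515,84.8,1856.25,309.58,2314.03,21.6
NTWC,2013,8309,3967,88.4,2410.10,360.06,1923.74,22.0
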