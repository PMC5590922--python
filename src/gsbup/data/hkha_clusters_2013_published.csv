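dmu_id,score,rts,s_DI1_excess,s_DI2_excess,s_UI1_shortfall,s_DO1_shortfall,s_DO2_shortfall,s_DO3_shortfall,s_UO1_excess,updated_score
HKEC,0.839,IRS,0.00,9.74,1.89,241.84,48.00,228.95,0.00,0.941
HKWC,0.754,IRS,0.00,9.06,1.52,508.21,72.97,276.84,0.00,0.972
KCC,0.913,DRS,984.85,392.57,0.25,274.36,146.76,0.00,4.21,1
KEC,1,CRS,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1
KWC,0.954,DRS,1627.82,761.76,0.25,418.85,431.40,0.00,3.89,1
NTEC,0.839,DRS,1026.85,459.20,0.23,281.37,202.46,0.00,3.12,0.966
NTWC,1,CRS,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1
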